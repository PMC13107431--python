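"""Read and write single-chain C-alpha structure models.

Models are exposed as ordered C-alpha traces with a per-residue confidence
value (pLDDT). Following the AlphaFold convention, pLDDT is stored in the
B-factor column of PDB/mmCIF files. Residues are renumbered 1..N internally
(file order); the original author numbering is kept in ``meta``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as bt_pdb
from biotite.structure.io import pdbx as bt_pdbx

from .errors import AmbiguityError, EmptyModelError, FormatError

logger = logging.getLogger(__name__)

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1_TO_3 = {v: k for k, v in _AA3_TO_1.items()}
_AA1_TO_3["X"] = "UNK"


@dataclass(frozen=True)
class Residue:
    """One residue of a C-alpha trace.

    Attributes
    ----------
    seq_index : int
        1-based position in the chain; strictly increasing within a model.
    aa : str
        One-letter amino-acid code (``X`` for unknown).
    ca_coord : np.ndarray
        C-alpha coordinate, shape (3,), in Angstrom.
    plddt : float
        Per-residue confidence in [0, 100].
    """

    seq_index: int
    aa: str
    ca_coord: np.ndarray
    plddt: float

    def __post_init__(self):
        coord = np.asarray(self.ca_coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError("ca_coord must be a finite 3-vector")
        object.__setattr__(self, "ca_coord", coord)
        if not (0.0 <= self.plddt <= 100.0):
            raise ValueError(f"plddt {self.plddt} outside [0, 100]")
        if self.seq_index < 1:
            raise ValueError("seq_index must be positive")


@dataclass
class StructureModel:
    """Ordered C-alpha trace of one chain with per-residue confidence."""

    model_id: str
    residues: list[Residue]
    label: str = ""
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.model_id:
            raise ValueError("model_id must be non-empty")
        if not self.label:
            self.label = self.model_id
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residues must have strictly increasing seq_index")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of C-alpha coordinates."""
        return np.array([r.ca_coord for r in self.residues], dtype=float)

    @property
    def plddt(self) -> np.ndarray:
        return np.array([r.plddt for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def subset(self, positions: Sequence[int]) -> "StructureModel":
        """New model keeping the residues at the given 1-based list positions.

        Positions refer to the current residue order (not seq_index); the
        surviving residues keep their seq_index values, so order stays
        strictly increasing.
        """
        keep = sorted(set(positions))
        if any(p < 1 or p > len(self.residues) for p in keep):
            raise IndexError("position outside model")
        return StructureModel(
            model_id=self.model_id,
            label=self.label,
            residues=[self.residues[p - 1] for p in keep],
            meta=dict(self.meta),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """New model with coordinates ``R x + t`` applied to every residue."""
        new = [
            replace(r, ca_coord=rotation @ r.ca_coord + np.asarray(translation, float))
            for r in self.residues
        ]
        return StructureModel(self.model_id, new, self.label, dict(self.meta))


def check_unique_ids(models: Sequence[StructureModel]) -> None:
    seen: set[str] = set()
    for m in models:
        if m.model_id in seen:
            raise ValueError(f"duplicate model_id {m.model_id!r} in dataset")
        seen.add(m.model_id)


def _model_from_atoms(atoms, chain: str | None, model_id: str) -> StructureModel:
    """Build a StructureModel from a biotite AtomArray."""
    amino = struc.filter_amino_acids(atoms)
    if not np.any(amino):
        raise EmptyModelError(f"{model_id}: no amino-acid residues found")
    poly = atoms[amino]
    chains = sorted(set(poly.chain_id))
    if chain is None:
        if len(chains) > 1:
            raise AmbiguityError(
                f"{model_id}: multiple chains {chains}; pass an explicit chain"
            )
        chain = chains[0]
    elif chain not in chains:
        raise EmptyModelError(f"{model_id}: chain {chain!r} not present (found {chains})")
    poly = poly[poly.chain_id == chain]

    n_res_total = struc.get_residue_count(poly)
    ca = poly[poly.atom_name == "CA"]
    if ca.array_length() == 0:
        raise EmptyModelError(f"{model_id}: no C-alpha atoms in chain {chain!r}")
    n_missing = n_res_total - ca.array_length()
    if n_missing > 0:
        logger.warning(
            "%s: %d residue(s) without a CA atom omitted", model_id, n_missing
        )

    bfac = np.asarray(ca.b_factor, dtype=float)
    if np.all(bfac == 0):
        logger.warning(
            "%s: all B-factors are 0; assuming an experimental structure and "
            "setting pLDDT = 100", model_id,
        )
        bfac = np.full(len(bfac), 100.0)
    bfac = np.clip(bfac, 0.0, 100.0)

    residues = []
    auth_numbers = []
    for i in range(ca.array_length()):
        aa = _AA3_TO_1.get(ca.res_name[i], "X")
        residues.append(
            Residue(seq_index=i + 1, aa=aa, ca_coord=ca.coord[i], plddt=float(bfac[i]))
        )
        ins = ca.ins_code[i] if "ins_code" in ca.get_annotation_categories() else ""
        auth_numbers.append(f"{ca.res_id[i]}{ins}".strip())
    meta = {"chain": chain, "auth_numbering": ",".join(auth_numbers)}
    return StructureModel(model_id=model_id, residues=residues, meta=meta)


def read_structure(path: str | Path, chain: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file as a single-chain C-alpha trace.

    pLDDT is taken from the B-factor field. The format is chosen by file
    extension (``.cif``/``.mmcif`` -> mmCIF, anything else -> PDB). Residues
    are renumbered 1..N in file order; author numbering goes to
    ``meta["auth_numbering"]``. Only the first altloc conformer is used.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".cif", ".mmcif"):
            cif = bt_pdbx.CIFFile.read(str(path))
            atoms = bt_pdbx.get_structure(
                cif, model=1, extra_fields=["b_factor"], altloc="first"
            )
        else:
            pdbf = bt_pdb.PDBFile.read(str(path))
            atoms = bt_pdb.get_structure(
                pdbf, model=1, extra_fields=["b_factor"], altloc="first"
            )
    except (EmptyModelError, AmbiguityError):
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return _model_from_atoms(atoms, chain, model_id=path.stem)


def write_structure(model: StructureModel, path: str | Path, format: str | None = None) -> None:
    """Write a model as a CA-only PDB or mmCIF file (pLDDT in B-factor).

    PDB output rounds coordinates to 3 decimals (format convention).
    """
    if len(model) == 0:
        raise EmptyModelError("refusing to write an empty model")
    path = Path(path)
    if format is None:
        format = "cif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format not in ("pdb", "cif"):
        raise ValueError(f"unknown format {format!r}")

    n = len(model)
    atoms = struc.AtomArray(n)
    atoms.coord = model.coords
    atoms.chain_id = np.full(n, model.meta.get("chain", "A"))
    atoms.res_id = np.array([r.seq_index for r in model.residues])
    atoms.res_name = np.array([_AA1_TO_3.get(r.aa, "UNK") for r in model.residues])
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.full(n, False)
    atoms.set_annotation("b_factor", model.plddt)
    atoms.set_annotation("occupancy", np.ones(n))

    if format == "pdb":
        out = bt_pdb.PDBFile()
        bt_pdb.set_structure(out, atoms)
    else:
        out = bt_pdbx.CIFFile()
        bt_pdbx.set_structure(out, atoms)
    out.write(str(path))
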