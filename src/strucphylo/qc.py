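"""pLDDT-based quality control for predicted structure models.

Three rules, applied in order:

1. Terminal trimming: slide a 15-residue window in from each terminus and cut
   everything outside the first/last window in which every residue has
   pLDDT > 70.
2. Rejection: on the trimmed model, reject if the fraction of residues with
   pLDDT < 50 exceeds 5%, or the fraction with pLDDT < 70 exceeds 10%
   (strictly "higher than": boundary models pass).
3. Removal: residues with pLDDT strictly below 50 are dropped from models
   that pass.

All thresholds are configurable; the defaults are the published rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyModelError, QCError
from .structio import StructureModel, check_unique_ids

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Per-model record of the QC outcome."""

    model_id: str
    n_before: int
    n_after_terminal_trim: int
    frac_below_50: float
    frac_below_70: float
    passed: bool
    n_removed_low: int = 0
    reasons: list[str] = field(default_factory=list)


def trim_termini(model: StructureModel, window: int = 15, threshold: float = 70.0) -> StructureModel:
    """Trim low-confidence termini.

    Returns the sub-model from the first position ``p`` such that all residues
    in ``[p, p+window-1]`` have pLDDT strictly above ``threshold``, through the
    last position ``q`` such that all of ``[q-window+1, q]`` qualify. If no
    window qualifies, an empty model (zero residues) is returned.
    """
    n = len(model)
    if n < window:
        raise QCError(f"{model.model_id}: too short for window ({n} < {window})")
    ok = model.plddt > threshold
    # all-true windows: run a moving sum over the boolean mask
    wsum = np.convolve(ok.astype(int), np.ones(window, dtype=int), mode="valid")
    starts = np.flatnonzero(wsum == window)  # 0-based window start positions
    if starts.size == 0:
        return StructureModel(model.model_id, [], model.label, dict(model.meta))
    p = int(starts[0]) + 1                   # first residue of first window
    q = int(starts[-1]) + window             # last residue of last window
    if p == 1 and q == n:
        return model
    return model.subset(range(p, q + 1))


def qc_filter(
    model: StructureModel,
    low: float = 50.0,
    mid: float = 70.0,
    max_low_frac: float = 0.05,
    max_mid_frac: float = 0.10,
) -> QCReport:
    """Pass/fail decision on a terminally trimmed model.

    Fails if the fraction of residues below ``low`` strictly exceeds
    ``max_low_frac``, or the fraction below ``mid`` strictly exceeds
    ``max_mid_frac``.
    """
    n = len(model)
    if n == 0:
        return QCReport(model.model_id, 0, 0, 0.0, 0.0, False,
                        reasons=["empty after trimming"])
    plddt = model.plddt
    f_low = float(np.mean(plddt < low))
    f_mid = float(np.mean(plddt < mid))
    reasons = []
    if f_low > max_low_frac:
        reasons.append(f"frac pLDDT<{low:g} = {f_low:.3f} > {max_low_frac:g}")
    if f_mid > max_mid_frac:
        reasons.append(f"frac pLDDT<{mid:g} = {f_mid:.3f} > {max_mid_frac:g}")
    return QCReport(model.model_id, n, n, f_low, f_mid, passed=not reasons,
                    reasons=reasons)


def drop_low_confidence(model: StructureModel, cutoff: float = 50.0) -> StructureModel:
    """Remove residues with pLDDT strictly below ``cutoff``, keeping order."""
    keep = [i + 1 for i, r in enumerate(model.residues) if r.plddt >= cutoff]
    if not keep:
        raise EmptyModelError(f"{model.model_id}: no residues with pLDDT >= {cutoff:g}")
    if len(keep) == len(model):
        return model
    return model.subset(keep)


def trim_to_region(model: StructureModel, start: int, end: int, margin: int = 200) -> StructureModel:
    """Keep residues in ``[start - margin, end + margin]`` (1-based positions).

    Used to restrict oversized models to an annotated domain plus a safety
    margin; a model already inside the window is returned unchanged.
    """
    n = len(model)
    if not (1 <= start <= end <= n):
        raise QCError(f"invalid region [{start}, {end}] for model of length {n}")
    lo = max(1, start - margin)
    hi = min(n, end + margin)
    if lo == 1 and hi == n:
        return model
    return model.subset(range(lo, hi + 1))


def qc_batch(
    models: list[StructureModel],
    window: int = 15,
    hi: float = 70.0,
    lo: float = 50.0,
    max_lo_frac: float = 0.05,
    max_hi_frac: float = 0.10,
) -> tuple[list[StructureModel], list[QCReport]]:
    """Run trim_termini -> qc_filter -> drop_low_confidence over a dataset.

    Returns the passing models (after low-confidence residue removal) and one
    QCReport per input model, in input order. Per-model failures are recorded,
    never raised.
    """
    check_unique_ids(models)
    passed_models: list[StructureModel] = []
    reports: list[QCReport] = []
    for m in models:
        n_before = len(m)
        try:
            trimmed = trim_termini(m, window=window, threshold=hi)
        except QCError as exc:
            reports.append(QCReport(m.model_id, n_before, n_before, 0.0, 0.0,
                                    False, reasons=[str(exc)]))
            continue
        rep = qc_filter(trimmed, low=lo, mid=hi,
                        max_low_frac=max_lo_frac, max_mid_frac=max_hi_frac)
        rep.n_before = n_before
        rep.n_after_terminal_trim = len(trimmed)
        if rep.passed:
            cleaned = drop_low_confidence(trimmed, cutoff=lo)
            rep.n_removed_low = len(trimmed) - len(cleaned)
            passed_models.append(cleaned)
        reports.append(rep)
    logger.info("QC: %d/%d models passed", len(passed_models), len(models))
    return passed_models, reports
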