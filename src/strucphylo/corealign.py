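"""Common-core structural alignment and all-against-all similarity scoring.

The aligner identifies structurally equivalent residues across a set of
C-alpha models without using sequence order: candidate superpositions are
seeded from gapless fragment pairs, extended by iterative closest-residue
assignment, and the per-structure correspondences are then merged
progressively (most similar groups first), intersecting the correspondences
so that every surviving column has exactly one residue in every member
structure. Because seeding and extension are purely geometric, circularly
permuted chains (segments swapped in sequence but not in space) align
correctly.

Scoring is column-additive: each aligned column contributes

    score(col) = w_geo * exp(-d^2 / (2 sigma^2)) + w_aa * aa_sim

where ``d`` is the inter-C-alpha distance after superposition and ``aa_sim``
is a BLOSUM62 value rescaled to [0, 1]. The self-score S(A,A) uses d = 0 for
every residue, so S(A,B) <= min(S(A,A), S(B,B)) holds column by column —
the property the score-to-distance conversion downstream relies on.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from biotite.sequence.align import SubstitutionMatrix

from .errors import AlignmentError
from .structio import StructureModel, check_unique_ids

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# amino-acid similarity: BLOSUM62 rescaled to [0, 1] over the 20 standard AAs
# ---------------------------------------------------------------------------

def _build_aa_similarity() -> dict[tuple[str, str], float]:
    mat = SubstitutionMatrix.std_protein_matrix()  # BLOSUM62
    aas = "ACDEFGHIKLMNPQRSTVWY"
    raw = {}
    for a in aas:
        for b in aas:
            raw[(a, b)] = mat.get_score(a, b)
    lo = min(raw.values())
    hi = max(raw.values())
    sim = {k: (v - lo) / (hi - lo) for k, v in raw.items()}
    return sim


_AA_SIM = _build_aa_similarity()


def aa_similarity(a: str, b: str) -> float:
    """BLOSUM62 similarity rescaled to [0, 1]; pairs involving X score 0."""
    return _AA_SIM.get((a, b), 0.0)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

@dataclass
class Superposition:
    """Optimal rigid-body fit of paired coordinate sets.

    ``rotation``/``translation`` map set A onto set B: x -> R x + t.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    pairs: list[tuple[int, int]] = field(default_factory=list)
    degenerate: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of paired point sets (Kabsch/SVD).

    Minimises the RMSD of ``R a_i + t`` against ``b_i`` over all proper
    rotations R and translations t. Near-collinear point sets give an
    unstable rotation about the axis; such fits are flagged ``degenerate``
    and a warning is logged.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coords must be matching (n, 3) arrays")
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 point pairs, got {n}")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (A @ R.T + t) - B
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    degenerate = bool(S[1] < 1e-8 * max(S[0], 1.0))
    if degenerate:
        logger.warning("kabsch_superpose: near-collinear points, rotation unstable")
    return Superposition(rotation=R, translation=t, rmsd=rmsd, degenerate=degenerate)


def _batch_fragment_rmsd(fr_a: np.ndarray, fr_b: np.ndarray) -> np.ndarray:
    """RMSD of optimal superposition for every fragment pair.

    fr_a: (Fa, L, 3), fr_b: (Fb, L, 3) -> (Fa, Fb) matrix, via batched SVD.
    """
    L = fr_a.shape[1]
    A = fr_a - fr_a.mean(axis=1, keepdims=True)
    B = fr_b - fr_b.mean(axis=1, keepdims=True)
    # covariance H[f, g] = A[f].T @ B[g]
    H = np.einsum("fli,glj->fgij", A, B)
    s = np.linalg.svd(H, compute_uv=False)  # (Fa, Fb, 3) descending
    detH = np.linalg.det(H)
    s3 = np.where(detH < 0, -s[..., 2], s[..., 2])
    e = (
        np.sum(A * A, axis=(1, 2))[:, None]
        + np.sum(B * B, axis=(1, 2))[None, :]
        - 2.0 * (s[..., 0] + s[..., 1] + s3)
    )
    return np.sqrt(np.maximum(e, 0.0) / L)


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignParams:
    """Tunable knobs of the geometric aligner (all distances in Angstrom)."""

    fragment_len: int = 12
    fragment_stride: int = 6
    seed_rmsd_max: float = 2.0
    max_seeds: int = 8
    pair_cutoff: float = 4.5
    sigma_score: float = 3.0
    w_geo: float = 1.0
    w_aa: float = 0.5
    min_core_len: int = 30
    max_iter: int = 50
    seed: int = 0


@dataclass
class PairAlignment:
    pairs: list[tuple[int, int]]      # (1-based pos in A, 1-based pos in B)
    score: float
    rmsd: float
    superposition: Superposition


def _column_scores(
    a: StructureModel, b: StructureModel,
    pairs_a: np.ndarray, pairs_b: np.ndarray,
    dists: np.ndarray, params: AlignParams,
) -> np.ndarray:
    geo = params.w_geo * np.exp(-(dists ** 2) / (2.0 * params.sigma_score ** 2))
    seq_a = a.sequence
    seq_b = b.sequence
    aa = np.array([aa_similarity(seq_a[i], seq_b[j])
                   for i, j in zip(pairs_a, pairs_b)])
    return geo + params.w_aa * aa


def self_score(model: StructureModel, params: AlignParams | None = None) -> float:
    """S(A,A): per-residue maxima (d = 0, own amino acid), summed."""
    params = params or AlignParams()
    return float(sum(params.w_geo + params.w_aa * aa_similarity(r.aa, r.aa)
                     for r in model.residues))


_FAR = 1e6


def _assign_pairs(dists: np.ndarray, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """One-to-one assignment among residue pairs closer than ``cutoff``.

    Minimum-cost (Hungarian) assignment over the admissible pairs; at
    divergences where a residue's nearest neighbour is not its true
    equivalent, the global optimum makes measurably fewer mismatches than
    greedy nearest-neighbour matching.
    """
    cost = np.where(dists < cutoff, dists, _FAR)
    ri, rj = linear_sum_assignment(cost)
    keep = cost[ri, rj] < cutoff
    return ri[keep], rj[keep]


def _extend_seed(
    A: np.ndarray, B: np.ndarray, init_a: np.ndarray, init_b: np.ndarray,
    params: AlignParams,
) -> tuple[np.ndarray, np.ndarray, Superposition] | None:
    """Iterative closest-residue refinement of a seed correspondence."""
    pa, pb = init_a, init_b
    prev: frozenset | None = None
    sup = None
    for _ in range(params.max_iter):
        sup = kabsch_superpose(A[pa], B[pb])
        dists = cdist(sup.apply(A), B)
        pa, pb = _assign_pairs(dists, params.pair_cutoff)
        if len(pa) < 3:
            return None
        cur = frozenset(zip(pa.tolist(), pb.tolist()))
        if cur == prev:
            break
        prev = cur
    sup = kabsch_superpose(A[pa], B[pb])
    return pa, pb, sup


def align_pair(a: StructureModel, b: StructureModel,
               params: AlignParams | None = None) -> PairAlignment:
    """Sequence-order-free pairwise structural alignment.

    Seeds from gapless 12-residue fragment superpositions, keeps
    geometrically distinct low-RMSD seeds, extends each by iterated rounds of
    superposition and one-to-one residue assignment, and returns the
    extension with the highest column-additive score.
    """
    params = params or AlignParams()
    if len(a) < params.min_core_len or len(b) < params.min_core_len:
        raise AlignmentError(
            f"models shorter than min_core_len={params.min_core_len}")
    A, B = a.coords, b.coords
    L = params.fragment_len
    starts_a = np.arange(0, len(a) - L + 1, params.fragment_stride)
    starts_b = np.arange(0, len(b) - L + 1, params.fragment_stride)
    fr_a = np.stack([A[s:s + L] for s in starts_a])
    fr_b = np.stack([B[s:s + L] for s in starts_b])
    frag_rmsd = _batch_fragment_rmsd(fr_a, fr_b)

    flat = np.argsort(frag_rmsd, axis=None)
    seeds: list[tuple[int, int]] = []
    seed_sups: list[Superposition] = []
    for k in flat:
        fa, fb = np.unravel_index(k, frag_rmsd.shape)
        if frag_rmsd[fa, fb] >= params.seed_rmsd_max and seeds:
            break
        sa, sb = starts_a[fa], starts_b[fb]
        sup = kabsch_superpose(A[sa:sa + L], B[sb:sb + L])
        # skip seeds whose whole transform is close to one already taken;
        # rotation alone is not enough: register shifts along repetitive
        # backbone (helix periods, serpentine rows) share the rotation but
        # differ in translation
        dup = any(
            np.arccos(np.clip((np.trace(s.rotation.T @ sup.rotation) - 1) / 2,
                              -1, 1)) < 0.17
            and np.linalg.norm(s.translation - sup.translation) < 3.0
            for s in seed_sups
        )
        if dup:
            continue
        seeds.append((sa, sb))
        seed_sups.append(sup)
        if len(seeds) >= params.max_seeds:
            break
    if not seeds:
        fa, fb = np.unravel_index(flat[0], frag_rmsd.shape)
        seeds = [(starts_a[fa], starts_b[fb])]

    best: PairAlignment | None = None
    for sa, sb in seeds:
        init = np.arange(L)
        res = _extend_seed(A, B, sa + init, sb + init, params)
        if res is None:
            continue
        pa, pb, sup = res
        dists = np.linalg.norm(sup.apply(A[pa]) - B[pb], axis=1)
        score = float(np.sum(_column_scores(a, b, pa, pb, dists, params)))
        if best is None or score > best.score:
            order = np.argsort(pa)
            pairs = [(int(pa[k]) + 1, int(pb[k]) + 1) for k in order]
            sup.pairs = pairs
            best = PairAlignment(pairs=pairs, score=score, rmsd=sup.rmsd,
                                 superposition=sup)
    if best is None or len(best.pairs) < params.min_core_len:
        got = 0 if best is None else len(best.pairs)
        raise AlignmentError(
            f"no correspondence of >= {params.min_core_len} residues between "
            f"{a.model_id} and {b.model_id} (best {got})")
    return best


# ---------------------------------------------------------------------------
# core alignment containers
# ---------------------------------------------------------------------------

@dataclass
class CoreColumn:
    """One column of structurally equivalent residues (1-based positions)."""

    members: dict[str, int]
    spread: float = 0.0


@dataclass
class CoreAlignment:
    columns: list[CoreColumn]
    model_ids: list[str]
    avg_rmsd: float = 0.0

    def __len__(self) -> int:
        return len(self.columns)

    def positions(self, model_id: str) -> np.ndarray:
        """0-based residue indices of ``model_id`` across columns."""
        return np.array([c.members[model_id] - 1 for c in self.columns], dtype=int)


@dataclass
class ScoreMatrix:
    """Symmetric all-against-all similarity with per-column contributions.

    ``contrib[i, j, c]`` is column c's contribution to S[i, j]; summing
    contributions over any column subset gives the score restricted to that
    subset (column additivity).
    """

    ids: list[str]
    S: np.ndarray
    contrib: np.ndarray | None = None

    def validate(self) -> None:
        if not np.allclose(self.S, self.S.T, atol=1e-9):
            raise ValueError("score matrix not symmetric")
        diag = np.diag(self.S)
        bound = np.minimum.outer(diag, diag)
        if np.any(self.S > bound + 1e-9):
            raise ValueError("self-score dominance violated")


# ---------------------------------------------------------------------------
# progressive merge
# ---------------------------------------------------------------------------

@dataclass
class _Group:
    members: list[int]                    # model indices
    columns: list[dict[int, int]]         # model index -> 1-based position


def _medoid(group: _Group, S0: np.ndarray) -> int:
    if len(group.members) == 1:
        return group.members[0]
    return max(group.members,
               key=lambda i: np.mean([S0[i, j] for j in group.members if j != i]))


def score_core(models: list[StructureModel], core: CoreAlignment,
               params: AlignParams | None = None) -> ScoreMatrix:
    """All-against-all scores restricted to the core columns.

    For each model pair the core-column coordinates are superposed once and
    per-column contributions recorded; the diagonal holds self-scores over the
    same columns.
    """
    params = params or AlignParams()
    by_id = {m.model_id: m for m in models}
    ms = [by_id[i] for i in core.model_ids]
    n = len(ms)
    ncol = len(core.columns)
    pos = [core.positions(m.model_id) for m in ms]
    seqs = [m.sequence for m in ms]
    contrib = np.zeros((n, n, ncol))
    for i in range(n):
        contrib[i, i] = params.w_geo + params.w_aa * np.array(
            [aa_similarity(seqs[i][p], seqs[i][p]) for p in pos[i]])
    for i, j in itertools.combinations(range(n), 2):
        Ai = ms[i].coords[pos[i]]
        Bj = ms[j].coords[pos[j]]
        sup = kabsch_superpose(Ai, Bj)
        d = np.linalg.norm(sup.apply(Ai) - Bj, axis=1)
        geo = params.w_geo * np.exp(-(d ** 2) / (2.0 * params.sigma_score ** 2))
        aa = np.array([aa_similarity(seqs[i][p], seqs[j][q])
                       for p, q in zip(pos[i], pos[j])])
        contrib[i, j] = contrib[j, i] = geo + params.w_aa * aa
    sm = ScoreMatrix(ids=list(core.model_ids), S=contrib.sum(axis=2), contrib=contrib)
    sm.validate()
    return sm


def _column_spreads(models: list[StructureModel], core: CoreAlignment,
                    S: np.ndarray) -> None:
    """Per-column RMS pairwise distance after joint superposition to the medoid."""
    n = len(core.model_ids)
    by_id = {m.model_id: m for m in models}
    mean_s = [np.mean([S[i, j] for j in range(n) if j != i]) for i in range(n)]
    ref = int(np.argmax(mean_s))
    pos = [core.positions(mid) for mid in core.model_ids]
    ref_xyz = by_id[core.model_ids[ref]].coords[pos[ref]]
    placed = []
    for i, mid in enumerate(core.model_ids):
        xyz = by_id[mid].coords[pos[i]]
        placed.append(kabsch_superpose(xyz, ref_xyz).apply(xyz))
    placed = np.stack(placed)  # (n_models, n_cols, 3)
    for c, col in enumerate(core.columns):
        pts = placed[:, c, :]
        diff = pts[:, None, :] - pts[None, :, :]
        sq = np.sum(diff ** 2, axis=2)
        iu = np.triu_indices(len(pts), k=1)
        col.spread = float(np.sqrt(np.mean(sq[iu]))) if iu[0].size else 0.0


def core_rmsd(core: CoreAlignment, models: list[StructureModel]) -> float:
    """Average over model pairs of the superposed RMSD on core columns."""
    if len(core.columns) == 0:
        raise AlignmentError("empty core")
    by_id = {m.model_id: m for m in models}
    vals = []
    for a_id, b_id in itertools.combinations(core.model_ids, 2):
        xa = by_id[a_id].coords[core.positions(a_id)]
        xb = by_id[b_id].coords[core.positions(b_id)]
        vals.append(kabsch_superpose(xa, xb).rmsd)
    return float(np.mean(vals)) if vals else 0.0


def build_core(models: list[StructureModel],
               params: AlignParams | None = None,
               strict: bool = False) -> tuple[CoreAlignment, ScoreMatrix]:
    """Progressive common-core construction over >= 3 models.

    All pairwise alignments are computed first; groups are then merged
    highest-score-first (group score = mean of member pairwise scores), each
    merge intersecting the two groups' correspondences via their medoid
    structures. Models that share fewer than ``min_core_len`` aligned
    residues with every other model are excluded with a warning (or raise
    under ``strict``).
    """
    params = params or AlignParams()
    check_unique_ids(models)
    if len(models) < 3:
        raise AlignmentError("need at least 3 models")

    n = len(models)
    S0 = np.zeros((n, n))
    pair_maps: dict[tuple[int, int], dict[int, int]] = {}
    for i, j in itertools.combinations(range(n), 2):
        try:
            al = align_pair(models[i], models[j], params)
        except AlignmentError:
            S0[i, j] = S0[j, i] = -np.inf
            pair_maps[(i, j)] = {}
            continue
        S0[i, j] = S0[j, i] = al.score
        pair_maps[(i, j)] = {pa: pb for pa, pb in al.pairs}

    # exclude models that align to nothing
    usable = []
    for i in range(n):
        best_len = max(
            (len(pair_maps[tuple(sorted((i, j)))]) for j in range(n) if j != i),
            default=0)
        if best_len < params.min_core_len:
            msg = (f"{models[i].model_id}: shares < {params.min_core_len} aligned "
                   f"residues with every other model")
            if strict:
                raise AlignmentError(msg)
            logger.warning("excluding %s", msg)
        else:
            usable.append(i)
    if len(usable) < 3:
        raise AlignmentError("fewer than 3 alignable models remain")

    def pmap(i: int, j: int) -> dict[int, int]:
        if i < j:
            return pair_maps[(i, j)]
        return {v: k for k, v in pair_maps[(j, i)].items()}

    groups = [
        _Group(members=[i],
               columns=[{i: p} for p in range(1, len(models[i]) + 1)])
        for i in usable
    ]

    def group_score(g: _Group, h: _Group) -> float:
        return float(np.mean([S0[i, j] for i in g.members for j in h.members]))

    while len(groups) > 1:
        best_pair, best_val, best_key = None, -np.inf, None
        for gi, hj in itertools.combinations(range(len(groups)), 2):
            v = group_score(groups[gi], groups[hj])
            key = tuple(sorted(
                models[i].model_id
                for i in groups[gi].members + groups[hj].members))
            if best_pair is None or v > best_val or (v == best_val and key < best_key):
                best_pair, best_val, best_key = (gi, hj), v, key
        gi, hj = best_pair
        g, h = groups[gi], groups[hj]
        # intersect correspondences via the most similar cross pair: their
        # pairwise alignment is the most reliable bridge between the groups
        mg, mh = max(
            ((i, j) for i in g.members for j in h.members),
            key=lambda ij: S0[ij[0], ij[1]],
        )
        corr = pmap(mg, mh)
        h_index = {col[mh]: col for col in h.columns}
        merged_cols = []
        for col in g.columns:
            q = corr.get(col[mg])
            if q is not None and q in h_index:
                merged = dict(col)
                merged.update(h_index[q])
                merged_cols.append(merged)
        new = _Group(members=sorted(g.members + h.members), columns=merged_cols)
        logger.debug("merged groups (%d + %d members) -> %d columns",
                     len(g.members), len(h.members), len(merged_cols))
        groups = [grp for k, grp in enumerate(groups) if k not in (gi, hj)]
        groups.append(new)

    final = groups[0]
    if len(final.columns) < params.min_core_len:
        raise AlignmentError(
            f"final core has only {len(final.columns)} columns "
            f"(min_core_len={params.min_core_len})")
    ids = [models[i].model_id for i in final.members]
    core = CoreAlignment(
        columns=[CoreColumn({models[i].model_id: p for i, p in col.items()})
                 for col in final.columns],
        model_ids=ids,
    )
    used_models = [m for m in models if m.model_id in set(ids)]
    scores = score_core(used_models, core, params)
    core.avg_rmsd = core_rmsd(core, used_models)
    _column_spreads(used_models, core, scores.S)
    logger.info("common core: %d columns over %d models (avg RMSD %.2f A)",
                len(core), len(ids), core.avg_rmsd)
    return core, scores


def restrict_scores(scores: ScoreMatrix, columns) -> ScoreMatrix:
    """Scores restricted to a subset of core columns (0-based indices).

    Column additivity makes this an exact partial sum of the stored
    per-column contributions; ``restrict_scores(all columns)`` equals the
    full matrix.
    """
    cols = np.asarray(sorted(set(int(c) for c in np.asarray(columns).ravel())))
    if cols.size == 0:
        raise ValueError("empty column subset")
    if scores.contrib is None:
        raise ValueError("score matrix carries no per-column contributions")
    ncol = scores.contrib.shape[2]
    if cols[0] < 0 or cols[-1] >= ncol:
        raise IndexError("column index outside core")
    sub = scores.contrib[:, :, cols]
    return ScoreMatrix(ids=list(scores.ids), S=sub.sum(axis=2), contrib=sub)
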