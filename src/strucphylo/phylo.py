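"""Distance-based tree inference and comparison.

Converts structural similarity scores to distances via

    D(A, B) = min(S(A,A), S(B,B)) - S(A,B),

infers unrooted trees with canonical neighbor joining (Saitou-Nei with the
Studier-Keppler Q-criterion), roots by outgroup, computes (normalized)
Robinson-Foulds distances from bipartition sets, and maps replicate support
onto a reference tree. Trees are backed by dendropy; Newick serialization
uses the internal-node-label-as-support dialect.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .errors import DominanceError, FormatError, TreeError

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    ids: list[str]
    D: np.ndarray

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.ids)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.D, self.D.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(self.D)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.D < -1e-12):
            bad = np.argwhere(self.D < -1e-12)[0]
            raise ValueError(
                f"negative distance between {self.ids[bad[0]]} and {self.ids[bad[1]]}")
        np.fill_diagonal(self.D, 0.0)
        self.D = np.maximum(self.D, 0.0)


class PhyloTree:
    """(Un)rooted tree with branch lengths and optional per-branch support.

    A thin wrapper over ``dendropy.Tree``. Leaf labels are taxon labels;
    support values (0-100) live on internal edges, serialized as internal
    node labels in Newick.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate leaf labels")

    # -- construction / serialization ------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            t = dendropy.Tree.get(data=newick, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
        except Exception as exc:
            raise FormatError(f"malformed Newick: {exc}") from exc
        return cls(t)

    def to_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True,
                                unquoted_underscores=True)
        return s.strip() + ("\n" if not s.endswith("\n") else "")

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.tree.clone(depth=1))

    # -- basic queries ----------------------------------------------------

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def __len__(self) -> int:
        return len(self.tree.leaf_nodes())

    def _nontrivial_nodes(self) -> list[dendropy.Node]:
        """Internal non-seed nodes whose edge induces a non-trivial bipartition."""
        n = len(self)
        out = []
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node or node.is_leaf():
                continue
            below = sum(1 for _ in node.leaf_iter())
            if 2 <= below <= n - 2:
                out.append(node)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the leaf set not containing the
        lexicographically smallest label (unrooted normalization)."""
        ref = min(self.leaf_labels())
        out = set()
        for node in self._nontrivial_nodes():
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in side:
                side = frozenset(set(self.leaf_labels()) - side)
            out.add(side)
        return out

    def supports(self) -> dict[frozenset, float]:
        """Support values keyed by bipartition (only labelled edges)."""
        ref = min(self.leaf_labels())
        all_leaves = set(self.leaf_labels())
        out = {}
        for node in self._nontrivial_nodes():
            if node.label is None:
                continue
            try:
                val = float(node.label)
            except ValueError:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in side:
                side = frozenset(all_leaves - side)
            out[side] = val
        return out


# ---------------------------------------------------------------------------
# score -> distance
# ---------------------------------------------------------------------------

def score_to_distance(scores) -> DistanceMatrix:
    """D(A,B) = min(S(A,A), S(B,B)) - S(A,B); requires self-score dominance.

    ``scores`` is any object with ``ids`` and a symmetric matrix ``S``.
    """
    S = np.asarray(scores.S, dtype=float)
    ids = list(scores.ids)
    diag = np.diag(S)
    D = np.minimum.outer(diag, diag) - S
    np.fill_diagonal(D, 0.0)
    if np.any(D < -1e-9):
        i, j = np.argwhere(D < -1e-9)[0]
        raise DominanceError(
            f"S({ids[i]},{ids[j]}) = {S[i, j]:.6g} exceeds "
            f"min of self-scores {min(diag[i], diag[j]):.6g}")
    D = np.maximum(D, 0.0)
    return DistanceMatrix(ids=ids, D=(D + D.T) / 2.0)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Canonical neighbor joining; exact on additive matrices.

    Negative branch lengths are clamped to zero and the clamped deficit is
    logged. The result is unrooted (trifurcating seed node).
    """
    n = len(dm.ids)
    if n < 3:
        raise TreeError(f"neighbor joining needs >= 3 taxa, got {n}")
    taxa = dendropy.TaxonNamespace(dm.ids)
    nodes = []
    for label in dm.ids:
        nd = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(nd)
    D = dm.D.copy()
    active = list(range(n))
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_s, j_s = np.unravel_index(np.argmin(Q), Q.shape)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        i, j = active[i_s], active[j_s]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_s] - r[j_s]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = clamp(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = clamp(lj)
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        k = len(nodes)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[k, :k] = new_row
        D[:k, k] = new_row
        D[k, k] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [k]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = clamp(ln)
    if clamped > 0:
        logger.debug("neighbor_joining: clamped %.4g of negative branch length",
                     clamped)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def root_with_outgroup(t: PhyloTree, outgroup: set[str]) -> PhyloTree:
    """Root on the edge separating ``outgroup`` from the remaining leaves."""
    outgroup = set(outgroup)
    labels = set(t.leaf_labels())
    missing = outgroup - labels
    if missing:
        raise TreeError(f"outgroup leaves not in tree: {sorted(missing)}")
    if not outgroup or outgroup == labels:
        raise TreeError("outgroup must be a proper non-empty leaf subset")
    new = t.copy()
    target = None
    for node in new.tree.preorder_node_iter():
        if node is new.tree.seed_node:
            continue
        below = set(lf.taxon.label for lf in node.leaf_iter())
        if below == outgroup or below == labels - outgroup:
            target = node
            break
    if target is None:
        raise TreeError(
            f"outgroup {sorted(outgroup)} is not separable by a single edge")
    edge = target.edge
    half = (edge.length or 0.0) / 2.0
    new.tree.reroot_at_edge(edge, length1=half, length2=half,
                            update_bipartitions=False)
    new.tree.is_rooted = True
    return PhyloTree(new.tree)


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------

def rf_distance(t1: PhyloTree, t2: PhyloTree, normalized: bool = False) -> float:
    """Robinson-Foulds distance: bipartitions present in exactly one tree.

    ``normalized`` divides by the maximum attainable value — the total number
    of non-trivial bipartitions in the two trees — giving a value in [0, 1]
    (two identical trees give 0; trees sharing no splits give 1).
    """
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise TreeError(
            f"leaf sets differ: only-in-t1={sorted(l1 - l2)}, "
            f"only-in-t2={sorted(l2 - l1)}")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    rf = len(b1 ^ b2)
    if not normalized:
        return float(rf)
    denom = len(b1) + len(b2)
    return rf / denom if denom else 0.0


# ---------------------------------------------------------------------------
# support mapping
# ---------------------------------------------------------------------------

def map_support(reference: PhyloTree, replicates: list[PhyloTree]) -> PhyloTree:
    """Annotate each internal edge of ``reference`` with the percentage of
    replicates containing the same bipartition (rounded to nearest integer).

    Topology and branch lengths of the reference are unchanged; invariant to
    replicate order and to replicate (re)rooting.
    """
    ref_leaves = set(reference.leaf_labels())
    for k, rep in enumerate(replicates):
        if set(rep.leaf_labels()) != ref_leaves:
            raise TreeError(f"replicate {k} has a different leaf set")
    rep_bips = [rep.bipartitions() for rep in replicates]
    out = reference.copy()
    helper = PhyloTree(out.tree)  # shares the cloned dendropy tree
    ref_label = min(reference.leaf_labels())
    for node in helper._nontrivial_nodes():
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref_label in side:
            side = frozenset(ref_leaves - side)
        cnt = sum(side in bips for bips in rep_bips)
        pct = 100.0 * cnt / len(replicates) if replicates else 0.0
        node.label = str(int(round(pct)))
    return helper


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> list[PhyloTree]:
    """Read one or more semicolon-terminated Newick trees from a file."""
    try:
        tl = dendropy.TreeList.get(path=str(path), schema="newick",
                                   suppress_internal_node_taxa=True,
                                   preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"malformed Newick in {path}: {exc}") from exc
    return [PhyloTree(t) for t in tl]


def write_newick(trees: PhyloTree | list[PhyloTree], path: str | Path,
                 header: str | None = None) -> None:
    if isinstance(trees, PhyloTree):
        trees = [trees]
    with open(path, "w") as fh:
        if header:
            fh.write(f"[{header}]\n")
        for t in trees:
            fh.write(t.to_newick())
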