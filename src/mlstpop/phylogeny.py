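"""Kimura two-parameter distances, neighbor joining, bootstrap support and
lineage-monophyly checks.

Neighbor joining is the Saitou–Nei agglomeration on the Q-criterion with a
deterministic tie-break (smallest active-index pair); it is consistent on
additive matrices, which the test suite exercises against randomly generated
trees.  Negative branch lengths are clamped to zero by default with the
deficit moved to the sister branch (standard practice), configurable to
``"keep"``.  Trees are scikit-bio ``TreeNode`` objects throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .errors import LabelingError, MatrixError, StatsError
from .scheme import seq_to_array

log = logging.getLogger(__name__)

_TRANSITION_PARTNER = np.array([2, 3, 0, 1], dtype=np.uint8)  # A<->G, C<->T


@dataclass
class K2PResult:
    p_transition: float
    q_transversion: float
    distance: float | None  # None when the correction is saturated


def k2p_distance(seq_a: str, seq_b: str) -> K2PResult:
    """Kimura two-parameter distance between two equal-length sequences.

    P is the fraction of sites with a transition difference (A<->G, C<->T),
    Q the fraction with a transversion difference;
    d = -(1/2) ln((1-2P-Q) sqrt(1-2Q)), ``None`` on saturation.
    """
    a = seq_to_array(seq_a)
    b = seq_to_array(seq_b)
    if a.size != b.size:
        raise StatsError("k2p_distance requires equal-length sequences")
    if a.size == 0:
        raise StatsError("k2p_distance on empty sequences")
    diff = a != b
    ts = int((diff & (_TRANSITION_PARTNER[a] == b)).sum())
    tv = int(diff.sum()) - ts
    P = ts / a.size
    Q = tv / a.size
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        log.warning("K2P saturated (P=%.4f, Q=%.4f); distance undefined", P, Q)
        return K2PResult(P, Q, None)
    return K2PResult(P, Q, -0.5 * math.log(arg1 * math.sqrt(arg2)))


def k2p_matrix(sequences: list[str]) -> np.ndarray:
    """Pairwise K2P distance matrix; raises on any saturated pair."""
    n = len(sequences)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = k2p_distance(sequences[i], sequences[j])
            if r.distance is None:
                raise MatrixError(
                    f"K2P distance saturated for sequence pair ({i}, {j})"
                )
            d[i, j] = d[j, i] = r.distance
    return d


def _validate_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise MatrixError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise MatrixError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise MatrixError("distance matrix must have a zero diagonal")
    if (d < 0).any():
        raise MatrixError("distance matrix has negative entries")
    return d


def neighbor_joining(
    distance_matrix: np.ndarray,
    ids: list[str],
    negative_branches: str = "clamp",
) -> TreeNode:
    """Neighbor joining on a symmetric distance matrix.

    Returns an unrooted tree represented with a trifurcating root.  Ties in
    the Q-criterion are broken by the smallest active-index pair, so the
    result is deterministic.  Three taxa are solved directly from the three
    pairwise equations.
    """
    d = _validate_matrix(distance_matrix)
    n = d.shape[0]
    if len(ids) != n:
        raise MatrixError(f"{len(ids)} ids for a {n}x{n} matrix")
    if n < 3:
        raise MatrixError("neighbor joining needs >= 3 taxa")
    nodes = [TreeNode(name=str(i)) for i in ids]
    d = d.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        q[np.tril_indices(m)] = np.inf
        # row-major argmin: exact ties resolve to the smallest index pair
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _fix_negative(li, lj, negative_branches)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        new_d[-1, : m - 2] = new_d[: m - 2, -1] = dk[keep]
        d = new_d
        nodes = [nodes[x] for x in keep] + [parent]

    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    if negative_branches == "clamp":
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode(children=[a, b, c])
    a.length, b.length, c.length = la, lb, lc
    return root


def _fix_negative(li: float, lj: float, mode: str) -> tuple[float, float]:
    if mode == "keep":
        return li, lj
    if mode != "clamp":
        raise ValueError("negative_branches must be 'clamp' or 'keep'")
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


# ------------------------------------------------------------ bipartitions

def _clades(tree: TreeNode) -> list[frozenset]:
    """Leaf-name set under every non-root node."""
    out = []
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            out.append(frozenset([node.name]))
        else:
            out.append(frozenset(t.name for t in node.tips()))
    return out


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalized as
    the side not containing the lexicographically smallest taxon."""
    taxa = frozenset(t.name for t in tree.tips())
    ref = min(taxa)
    out = set()
    for clade in _clades(tree):
        side = clade if ref not in clade else taxa - clade
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(side)
    return out


def bootstrap_support(
    alignment: list[str],
    ids: list[str],
    n_replicates: int = 1000,
    seed: int | None = None,
    negative_branches: str = "clamp",
) -> TreeNode:
    """NJ tree on K2P distances with bootstrap support percentages.

    Columns are resampled with replacement per replicate; support of each
    internal bipartition of the point-estimate tree is the percentage of
    replicates containing it.  Degenerate replicates (all sequences
    identical, or a saturated distance) are skipped, logged, and still
    counted in the denominator.  Deterministic under ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(alignment) < 4:
        raise StatsError("bootstrap support needs >= 4 taxa")
    mat = np.vstack([seq_to_array(s) for s in alignment])
    point = neighbor_joining(k2p_matrix(alignment), ids, negative_branches)
    target = bipartitions(point)
    hits = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    skipped = 0
    L = mat.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = mat[:, cols]
        seqs = ["".join("ACGT"[c] for c in row) for row in rep]
        if len(set(seqs)) == 1:
            skipped += 1
            continue
        try:
            t = neighbor_joining(k2p_matrix(seqs), ids, negative_branches)
        except MatrixError:
            skipped += 1
            continue
        reps = bipartitions(t)
        for bp in target:
            if bp in reps:
                hits[bp] += 1
    if skipped:
        log.warning("bootstrap: skipped %d degenerate replicate(s)", skipped)
    support = {bp: 100.0 * h / n_replicates for bp, h in hits.items()}
    taxa = frozenset(ids)
    ref = min(taxa)
    for node in point.postorder(include_self=False):
        if node.is_tip():
            continue
        clade = frozenset(t.name for t in node.tips())
        side = clade if ref not in clade else taxa - clade
        if side in support:
            node.support = support[side]
            node.name = str(int(round(support[side])))
    return point


def check_group_monophyly(
    tree: TreeNode, label_map: dict[str, str]
) -> dict[str, bool]:
    """For each label, is there an edge of the unrooted tree splitting
    exactly that label's leaves from the rest?"""
    taxa = frozenset(t.name for t in tree.tips())
    unlabeled = taxa - set(label_map)
    if unlabeled:
        raise LabelingError(f"unlabeled leaves: {sorted(unlabeled)}")
    clades = set(_clades(tree))
    out: dict[str, bool] = {}
    for label in sorted(set(label_map.values())):
        group = frozenset(t for t in taxa if label_map[t] == label)
        out[label] = (
            len(group) == 1
            or group == taxa
            or group in clades
            or (taxa - group) in clades
        )
    return out
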