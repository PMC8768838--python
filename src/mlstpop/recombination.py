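"""Recombination detection: a PHI-style permutation test, a clustered-SNP
segment scanner, and a transparent r/m summary.

The PHI-style statistic is the mean 0/1 incompatibility over pairs of
parsimony-informative sites whose alignment positions lie within ``w`` bp of
each other.  Two sites are compatible when they admit a common genealogy
without homoplasy, decided by acyclicity of the bipartite graph joining the
states of the two columns (the four-gamete test in the biallelic case).
Significance comes from permuting the positions of the informative columns,
with the add-one estimator, so a recombination-induced excess of *nearby*
incompatible pairs is what the test detects.

The segment scanner is a simple, fully documented clustered-SNP method (not
a reimplementation of model-based recombination inference): within each
labeled subgroup, SNPs are called between the subgroup consensus and the
consensus of all other isolates, and sliding windows whose SNP count is
binomially improbable under the subgroup's genome-wide SNP rate are merged
into maximal segments.  ``r_over_m_simple`` partitions segregating sites by
segment membership — a transparent analogue of r/m, not a model-based
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import PhiTestError, ScanError, StatsError
from .scheme import seq_to_array


def _codes_matrix(alignment: list[str]) -> np.ndarray:
    if not alignment:
        raise ScanError("empty alignment")
    lengths = {len(s) for s in alignment}
    if len(lengths) != 1:
        raise StatsError(f"unequal sequence lengths {sorted(lengths)}")
    return np.vstack([seq_to_array(s) for s in alignment])


def site_compatibility(column_i, column_j) -> bool:
    """True iff two sites admit a common homoplasy-free genealogy.

    Decided by acyclicity of the bipartite state-intersection graph: one
    node per observed state of each column, one edge per jointly observed
    state pair.  For two biallelic columns this is exactly the four-gamete
    test.  Symmetric by construction.
    """
    pairs = set(zip(column_i, column_j))
    nodes: dict[tuple[int, object], tuple[int, object]] = {}

    def find(x):
        while nodes[x] != x:
            nodes[x] = nodes[nodes[x]]
            x = nodes[x]
        return x

    for a, b in pairs:
        u, v = (0, a), (1, b)
        for node in (u, v):
            if node not in nodes:
                nodes[node] = node
        ru, rv = find(u), find(v)
        if ru == rv:
            return False  # edge closes a cycle
        nodes[ru] = rv
    return True


def informative_site_positions(m: np.ndarray) -> np.ndarray:
    """Positions of parsimony-informative columns (>= 2 states, each carried
    by >= 2 sequences)."""
    out = []
    for j in range(m.shape[1]):
        counts = np.bincount(m[:, j], minlength=4)
        if (counts >= 2).sum() >= 2:
            out.append(j)
    return np.asarray(out, dtype=np.int64)


@dataclass
class PhiResult:
    phi_statistic: float
    w: int
    n_informative_sites: int
    n_permutations: int
    seed: int | None
    p_value: float


def phi_test(
    alignment: list[str],
    w: int = 100,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> PhiResult:
    """PHI-style permutation test for recombination.

    ``w`` is the pairing window in alignment positions (bp).  The null
    distribution reassigns the observed informative columns to a random
    permutation of their positions; p-value uses the add-one estimator
    ``(1 + #{permuted >= observed}) / (1 + n_permutations)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    m = _codes_matrix(alignment)
    pos = informative_site_positions(m)
    k = pos.size
    if k < 2:
        raise PhiTestError(
            f"insufficient informative sites for the phi test (found {k}, need >= 2)"
        )
    cols = m[:, pos]
    incompat = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            bad = not site_compatibility(cols[:, i], cols[:, j])
            incompat[i, j] = incompat[j, i] = bad

    iu = np.triu_indices(k, 1)

    def statistic(p: np.ndarray) -> float:
        d = np.abs(p[:, None] - p[None, :])
        mask = d[iu] <= w
        if not mask.any():
            return 0.0
        return float(incompat[iu][mask].mean())

    observed = statistic(pos)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if statistic(rng.permutation(pos)) >= observed - 1e-12:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_permutations)
    return PhiResult(observed, w, k, n_permutations, seed, p_value)


# ------------------------------------------------------------ segment scan

@dataclass
class RecombinantSegment:
    start: int  # 0-based half-open on the concatenated alignment
    end: int
    label: str  # subgroup (ST or isolate set label) carrying the segment
    snps_inside: int
    background_rate: float
    score: float  # smallest binomial tail probability among flagged windows


def _consensus(m: np.ndarray) -> np.ndarray:
    """Per-column majority base; ties broken by alphabetical base (A<C<G<T,
    i.e. the smallest code — np.argmax takes the first maximum)."""
    counts = np.stack([(m == b).sum(axis=0) for b in range(4)])
    return counts.argmax(axis=0).astype(np.uint8)


def scan_recombinant_segments(
    alignment: list[str],
    group_labels: list[str],
    window_bp: int = 200,
    score_cutoff: float = 1e-6,
    max_gap: int | None = None,
) -> list[RecombinantSegment]:
    """Scan for clustered-SNP segments, per labeled subgroup.

    For each distinct label with a nonempty complement, SNPs are the
    positions where the subgroup consensus differs from the complement
    consensus.  All windows of ``window_bp`` (step 1) are scored by the
    binomial tail probability of their SNP count given the subgroup's
    alignment-wide SNP rate; windows under ``score_cutoff`` are merged, and
    within each merged region the densest SNP cluster (consecutive SNPs
    separated by at most ``max_gap`` bp, default ``window_bp // 2``) defines
    the reported interval — this trims away isolated background SNPs caught
    at the flanks of a flagged region.

    The complement consensus stands in for the subgroup's clonal background,
    so the scan is meant to run within one population/lineage at a time;
    donor material imported from a diverged population then shows up as a
    locally dense SNP run.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if max_gap is None:
        max_gap = max(1, window_bp // 2)
    m = _codes_matrix(alignment)
    n, L = m.shape
    if len(group_labels) != n:
        raise ScanError(
            f"{len(group_labels)} labels for {n} sequences"
        )
    window = min(window_bp, L)
    labels = sorted(set(group_labels))
    segments: list[RecombinantSegment] = []
    arr_labels = np.asarray(group_labels)
    for lab in labels:
        inside = arr_labels == lab
        if inside.all():
            continue
        snp_pos = np.nonzero(_consensus(m[inside]) != _consensus(m[~inside]))[0]
        if snp_pos.size == 0:
            continue
        rate = snp_pos.size / L
        ind = np.zeros(L, dtype=np.int64)
        ind[snp_pos] = 1
        csum = np.concatenate([[0], np.cumsum(ind)])
        starts = np.arange(0, L - window + 1)
        counts = csum[starts + window] - csum[starts]
        scores = sps.binom.sf(counts - 1, window, rate)
        flagged = np.nonzero(scores < score_cutoff)[0]
        if flagged.size == 0:
            continue
        # merge runs of flagged windows (overlapping or adjacent coverage)
        runs: list[list[int]] = [[int(flagged[0]), int(flagged[0])]]
        for s in flagged[1:]:
            if s <= runs[-1][1] + window:
                runs[-1][1] = int(s)
            else:
                runs.append([int(s), int(s)])
        for s0, s1 in runs:
            lo, hi = s0, s1 + window  # covered interval
            in_run = snp_pos[(snp_pos >= lo) & (snp_pos < hi)]
            if in_run.size == 0:
                continue
            # densest max-gap cluster of SNPs within the covered region
            breaks = np.nonzero(np.diff(in_run) > max_gap)[0]
            clusters = np.split(in_run, breaks + 1)
            cluster = max(clusters, key=len)
            segments.append(
                RecombinantSegment(
                    start=int(cluster[0]),
                    end=int(cluster[-1]) + 1,
                    label=lab,
                    snps_inside=int(cluster.size),
                    background_rate=rate,
                    score=float(scores[s0 : s1 + 1].min()),
                )
            )
    segments.sort(key=lambda s: (s.start, s.end, s.label))
    return segments


@dataclass
class RmEstimate:
    n_snps_in_segments: int
    n_snps_outside: int
    r_over_m_simple: float  # math.inf sentinel when all SNPs fall in segments


def estimate_r_over_m(
    alignment: list[str], segments: list[RecombinantSegment]
) -> RmEstimate:
    """Partition segregating sites by segment membership and take the ratio.

    This is the package's transparent SNP-partition analogue of r/m
    (``r_over_m_simple``), not a model-based estimate.
    """
    m = _codes_matrix(alignment)
    seg_sites = np.nonzero((m != m[0]).any(axis=0))[0]
    covered = np.zeros(m.shape[1], dtype=bool)
    for s in segments:
        covered[s.start : s.end] = True
    inside = int(covered[seg_sites].sum())
    outside = int(seg_sites.size - inside)
    if inside == 0:
        ratio = 0.0
    elif outside == 0:
        ratio = float("inf")
    else:
        ratio = inside / outside
    return RmEstimate(inside, outside, ratio)
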