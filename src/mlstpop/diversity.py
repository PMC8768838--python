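"""Per-locus and concatenated diversity and selection statistics.

Implements the classic summary-statistic family reported for housekeeping
MLST fragments: allele counts, segregating (polymorphic) sites, pooled GC
content, nucleotide diversity pi (mean pairwise differences per site),
Tajima's D with its full constant breakdown, and Nei–Gojobori (1986)
dN/dS with equal-weight pathway counting and Jukes–Cantor correction.

Undefined statistics (D with no segregating sites, dN/dS with dS = 0) are
``None`` sentinels, rendered as ``NA`` in output tables — never silent
zeros.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .errors import AlignmentError, StatsError
from .io import IsolateRecord
from .scheme import BASES, LocusScheme, seq_to_array

log = logging.getLogger(__name__)


def _codes_matrix(alignment: list[str]) -> np.ndarray:
    if not alignment:
        raise StatsError("empty alignment")
    lengths = {len(s) for s in alignment}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal sequence lengths {sorted(lengths)}")
    return np.vstack([seq_to_array(s) for s in alignment])


def gc_content(sequences: list[str]) -> float:
    """Fraction of G+C bases pooled over all sequences."""
    if not sequences or all(len(s) == 0 for s in sequences):
        raise StatsError("gc_content of empty input")
    g = c = total = 0
    for s in sequences:
        codes = seq_to_array(s)
        c += int((codes == 1).sum())
        g += int((codes == 2).sum())
        total += codes.size
    return (g + c) / total


def segregating_sites(alignment: list[str]) -> int:
    """Number of columns with more than one base observed."""
    m = _codes_matrix(alignment)
    if m.shape[0] < 2:
        raise StatsError("segregating_sites needs >= 2 sequences")
    return int((m != m[0]).any(axis=0).sum())


def _column_pair_diffs(m: np.ndarray) -> float:
    """Sum over columns of the number of differing sequence pairs."""
    n, L = m.shape
    npairs = n * (n - 1) // 2
    total = 0.0
    for b in range(4):
        cb = (m == b).sum(axis=0)
        total += (cb * (cb - 1) // 2).sum()
    return npairs * L - total


def nucleotide_diversity(alignment: list[str]) -> float:
    """pi: mean pairwise Hamming distance per site over all sequence pairs."""
    m = _codes_matrix(alignment)
    n, L = m.shape
    if n < 2:
        raise StatsError("nucleotide_diversity needs >= 2 sequences")
    npairs = n * (n - 1) // 2
    return _column_pair_diffs(m) / (npairs * L)


@dataclass
class TajimaBreakdown:
    """Tajima's D with the 1989 constants exposed for auditing."""

    n: int
    S: int
    pi_total: float  # mean pairwise differences per sequence pair (not per site)
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float | None


def tajimas_d(alignment: list[str]) -> TajimaBreakdown:
    """Tajima's D from pi and the number of segregating sites.

    D is ``None`` (not an exception) when S = 0.  Fewer than four sequences
    raise :class:`StatsError`.
    """
    m = _codes_matrix(alignment)
    n, L = m.shape
    if n < 4:
        raise StatsError(f"insufficient sequences for Tajima's D (n={n} < 4)")
    S = int((m != m[0]).any(axis=0).sum())
    npairs = n * (n - 1) // 2
    pi_total = _column_pair_diffs(m) / npairs

    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    if S == 0:
        D = None
    else:
        D = (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return TajimaBreakdown(n, S, pi_total, a1, a2, b1, b2, c1, c2, e1, e2, D)


# ------------------------------------------------------- Nei–Gojobori 1986

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate(codon: str) -> str:
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


def _syn_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (sum over the three positions
    of the fraction of the three possible substitutions that preserve the
    amino acid; substitutions to stop codons count as nonsynonymous)."""
    aa = _translate(codon)
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _translate(alt) == aa and aa != "*":
                s += 1.0 / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (nonsynonymous, synonymous) difference counts over all
    minimal substitution pathways between two codons, each pathway weighted
    equally.  Pathways passing through a stop codon are excluded unless all
    are blocked."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur = c1
        nd = sd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            aa_from, aa_to = _translate(cur), _translate(nxt)
            if aa_to == "*" and pos != order[-1]:
                blocked = True
            if aa_from == aa_to and aa_from != "*":
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        results.append((blocked, nd, sd))
    open_paths = [(nd, sd) for blocked, nd, sd in results if not blocked]
    if not open_paths:
        open_paths = [(nd, sd) for _, nd, sd in results]
    nd = sum(x for x, _ in open_paths) / len(open_paths)
    sd = sum(x for _, x in open_paths) / len(open_paths)
    return nd, sd


_SYN_CACHE: dict[str, float] = {}
_PATH_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _syn(codon: str) -> float:
    if codon not in _SYN_CACHE:
        _SYN_CACHE[codon] = _syn_fraction(codon)
    return _SYN_CACHE[codon]


def _paths(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2) if c1 <= c2 else (c2, c1)
    if key not in _PATH_CACHE:
        _PATH_CACHE[key] = _pathway_counts(*key)
    return _PATH_CACHE[key]


@dataclass
class NeiGojoboriResult:
    n_codons: int
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float | None
    dS: float | None
    ratio: float | None  # None when dS is 0 or undefined


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0  # avoid -0.0


def nei_gojobori(alignment: list[str], frame_offset: int = 0) -> NeiGojoboriResult:
    """Nei–Gojobori dN/dS over all sequence pairs.

    The reading frame starts at ``frame_offset``; the trailing partial codon
    is truncated.  Codon columns containing a stop codon in any sequence are
    excluded with a warning, keeping pairwise site counts comparable.  Site
    and difference counts are averaged over all pairs; proportions are
    Jukes–Cantor corrected.  ``ratio`` is ``None`` when dS = 0.
    """
    m = _codes_matrix(alignment)
    n, L = m.shape
    if n < 2:
        raise StatsError("nei_gojobori needs >= 2 sequences")
    usable = L - frame_offset
    n_codons = usable // 3
    if n_codons < 1:
        raise StatsError("alignment shorter than one codon after framing")
    seqs = [s.upper()[frame_offset : frame_offset + 3 * n_codons] for s in alignment]
    codons = [[s[3 * i : 3 * i + 3] for i in range(n_codons)] for s in seqs]

    keep = []
    dropped = 0
    for j in range(n_codons):
        if any(_translate(codons[i][j]) == "*" for i in range(n)):
            dropped += 1
        else:
            keep.append(j)
    if dropped:
        log.warning("nei_gojobori: excluded %d codon column(s) containing stops", dropped)
    if not keep:
        raise StatsError("no stop-free codon columns for dN/dS")

    syn_per_seq = [sum(_syn(codons[i][j]) for j in keep) for i in range(n)]
    total_sites = 3.0 * len(keep)

    sum_N = sum_S = sum_Nd = sum_Sd = 0.0
    npairs = 0
    for i in range(n):
        for k in range(i + 1, n):
            S_sites = 0.5 * (syn_per_seq[i] + syn_per_seq[k])
            N_sites = total_sites - S_sites
            nd = sd = 0.0
            for j in keep:
                if codons[i][j] != codons[k][j]:
                    d_nd, d_sd = _paths(codons[i][j], codons[k][j])
                    nd += d_nd
                    sd += d_sd
            sum_N += N_sites
            sum_S += S_sites
            sum_Nd += nd
            sum_Sd += sd
            npairs += 1

    N_sites = sum_N / npairs
    S_sites = sum_S / npairs
    Nd = sum_Nd / npairs
    Sd = sum_Sd / npairs
    pN = Nd / N_sites if N_sites > 0 else 0.0
    pS = Sd / S_sites if S_sites > 0 else 0.0
    dN = _jukes_cantor(pN)
    dS = _jukes_cantor(pS)
    if dN == 0.0 and Sd > 0.0:
        ratio = 0.0  # no nonsynonymous divergence at all
    elif dS is None or dN is None or dS == 0.0:
        ratio = None
    else:
        ratio = dN / dS
    return NeiGojoboriResult(
        len(keep), N_sites, S_sites, Nd, Sd, pN, pS, dN, dS, ratio
    )


# ------------------------------------------------------------ Table builder

STATS_COLUMNS = (
    "locus",
    "length",
    "n_alleles",
    "polymorphic_sites",
    "gc",
    "tajima_D",
    "phi_p",
    "pi",
    "dn_ds",
)


def stats_table(
    records: list[IsolateRecord],
    scheme: LocusScheme,
    phi_p: dict[str, float] | None = None,
    unique_alleles: bool = False,
) -> pd.DataFrame:
    """One row of summary statistics per locus plus a concatenated row.

    By default statistics run over all isolate sequences; with
    ``unique_alleles=True`` each distinct sequence is counted once.  The
    concatenated row's allele count is the number of distinct concatenated
    sequences, i.e. the number of STs.  ``phi_p`` (locus -> p-value, with key
    ``"concatenated"`` for the last row) fills the recombination column.
    """
    phi_p = phi_p or {}
    rows = []
    concat_seqs = [r.concatenated(scheme) for r in records]
    per_locus = {
        name: [r.sequences[name] for r in records] for name in scheme.names
    }
    for name in scheme.names:
        locus_def = scheme.get(name)
        seqs = per_locus[name]
        rows.append(
            _stats_row(
                name, locus_def.trimmed_length, seqs, locus_def.frame_offset,
                phi_p.get(name), unique_alleles,
            )
        )
    rows.append(
        _stats_row(
            "concatenated", scheme.concatenated_length, concat_seqs, 0,
            phi_p.get("concatenated"), unique_alleles,
        )
    )
    return pd.DataFrame(rows, columns=list(STATS_COLUMNS))


def _stats_row(name, length, seqs, frame_offset, phi, unique_alleles):
    n_alleles = len(set(seqs))
    work = sorted(set(seqs)) if unique_alleles else seqs
    row = {
        "locus": name,
        "length": length,
        "n_alleles": n_alleles,
        "polymorphic_sites": segregating_sites(work) if len(work) >= 2 else 0,
        "gc": gc_content(work),
        "tajima_D": np.nan,
        "phi_p": phi if phi is not None else np.nan,
        "pi": nucleotide_diversity(work) if len(work) >= 2 else 0.0,
        "dn_ds": np.nan,
    }
    if len(work) >= 4:
        D = tajimas_d(work).D
        row["tajima_D"] = np.nan if D is None else D
    if len(work) >= 2:
        ratio = nei_gojobori(work, frame_offset).ratio
        row["dn_ds"] = np.nan if ratio is None else ratio
    return row
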