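"""Allele calling and sequence-type assignment.

Alleles and STs are arbitrary labels: this module assigns them
deterministically in first-seen input order (the published datasets were
numbered by typing software with no stated order), so re-typing the same
input always yields identical catalogs and tables.  All downstream
statistics are invariant under relabeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LocusMismatchError, TrimError, TypingError
from .io import IsolateRecord
from .scheme import LocusDef, LocusScheme, array_to_seq, seq_to_array

N_LOCI = 6


@dataclass(frozen=True)
class AllelicProfile:
    """Six allele numbers in canonical locus order."""

    isolate_id: str
    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) != N_LOCI:
            raise TypingError(
                f"profile for {self.isolate_id} has {len(self.alleles)} loci, "
                f"expected {N_LOCI}"
            )
        if any(a < 1 for a in self.alleles):
            raise TypingError(f"profile for {self.isolate_id} has allele < 1")


class AlleleCatalog:
    """Per-locus injective mapping sequence -> allele number.

    Numbers are contiguous from 1 in first-seen order.  A catalog may be
    preloaded (e.g. from an existing allele database FASTA) and extended
    with novel alleles as they appear.
    """

    def __init__(self, scheme: LocusScheme):
        self.scheme = scheme
        self._maps: dict[str, dict[str, int]] = {n: {} for n in scheme.names}

    def assign(self, locus: str, seq: str) -> int:
        """Return the allele number for ``seq``, extending the catalog on a
        novel sequence.  Input is normalized to uppercase; ambiguity codes
        abort the call rather than minting a spurious allele."""
        locus_def = self.scheme.get(locus)
        seq = array_to_seq(seq_to_array(seq, context=f"{locus} allele"))
        if len(seq) != locus_def.trimmed_length:
            raise TypingError(
                f"{locus}: sequence length {len(seq)} != trimmed length "
                f"{locus_def.trimmed_length}"
            )
        table = self._maps[locus]
        if seq not in table:
            table[seq] = len(table) + 1
        return table[seq]

    def lookup(self, locus: str, seq: str) -> int | None:
        return self._maps[locus].get(seq.upper())

    def n_alleles(self, locus: str) -> int:
        return len(self._maps[locus])

    def sequences(self, locus: str) -> dict[str, int]:
        return dict(self._maps[locus])


class STTable:
    """Bijection between distinct allelic profiles and ST numbers, plus the
    ST -> isolate mapping.  ST numbers are contiguous from 1 in first-seen
    order."""

    def __init__(self) -> None:
        self._profile_to_st: dict[tuple[int, ...], int] = {}
        self._st_to_isolates: dict[int, list[str]] = {}
        self._st_to_profile: dict[int, tuple[int, ...]] = {}

    def add(self, profile: AllelicProfile) -> int:
        key = profile.alleles
        st = self._profile_to_st.get(key)
        if st is None:
            st = len(self._profile_to_st) + 1
            self._profile_to_st[key] = st
            self._st_to_profile[st] = key
            self._st_to_isolates[st] = []
        self._st_to_isolates[st].append(profile.isolate_id)
        return st

    def st_of(self, profile: AllelicProfile) -> int:
        try:
            return self._profile_to_st[profile.alleles]
        except KeyError:
            raise TypingError(
                f"profile {profile.alleles} has no assigned ST"
            ) from None

    def profile_of(self, st: int) -> tuple[int, ...]:
        if st not in self._st_to_profile:
            raise TypingError(f"unknown ST {st}")
        return self._st_to_profile[st]

    def isolates_of(self, st: int) -> list[str]:
        if st not in self._st_to_isolates:
            raise TypingError(f"unknown ST {st}")
        return list(self._st_to_isolates[st])

    @property
    def sts(self) -> list[int]:
        return sorted(self._st_to_profile)

    @property
    def n_sts(self) -> int:
        return len(self._st_to_profile)

    @property
    def n_isolates(self) -> int:
        return sum(len(v) for v in self._st_to_isolates.values())


def trim_to_scheme(raw_seq: str, locus: LocusDef, min_identity: float = 0.80) -> str:
    """Trim a raw locus sequence to the scheme frame.

    An exact-length input is returned unchanged.  A longer input is scanned
    for the window of ``trimmed_length`` with minimum Hamming distance to the
    locus reference allele (leftmost wins ties); a best window below the
    identity floor raises :class:`LocusMismatchError`.
    """
    codes = seq_to_array(raw_seq, context=f"{locus.name} raw sequence")
    L = locus.trimmed_length
    if codes.size < L:
        raise TrimError(
            f"{locus.name}: raw length {codes.size} shorter than scheme "
            f"length {L}"
        )
    if codes.size == L:
        return array_to_seq(codes)
    if not locus.reference_allele:
        raise TrimError(
            f"{locus.name}: trimming a longer sequence requires a scheme "
            "reference allele"
        )
    ref = seq_to_array(locus.reference_allele)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    dists = (windows != ref).sum(axis=1)
    best = int(np.argmin(dists))  # argmin returns the leftmost minimum
    identity = 1.0 - dists[best] / L
    if identity < min_identity:
        raise LocusMismatchError(
            f"{locus.name}: best trim window identity {identity:.3f} below "
            f"floor {min_identity:.2f}"
        )
    return array_to_seq(windows[best])


def assign_allele(catalog: AlleleCatalog, locus: str, seq: str) -> int:
    """Functional wrapper over :meth:`AlleleCatalog.assign`."""
    return catalog.assign(locus, seq)


def assign_sts(profiles: list[AllelicProfile]) -> STTable:
    """Number distinct profiles as STs in first-appearance order."""
    table = STTable()
    for p in profiles:
        table.add(p)
    return table


def profile_distance(p1: AllelicProfile, p2: AllelicProfile) -> int:
    """Number of loci at which two profiles carry different alleles (0-6)."""
    return sum(a != b for a, b in zip(p1.alleles, p2.alleles))


def type_dataset(
    records: list[IsolateRecord],
    scheme: LocusScheme,
    catalog: AlleleCatalog | None = None,
    trim: bool = False,
    min_identity: float = 0.80,
) -> tuple[list[AllelicProfile], STTable, AlleleCatalog]:
    """Allele-call and ST-assign a complete dataset.

    With ``trim=True`` raw sequences longer than the scheme length are first
    trimmed against the scheme references.
    """
    if catalog is None:
        catalog = AlleleCatalog(scheme)
    profiles: list[AllelicProfile] = []
    for rec in records:
        missing = [n for n in scheme.names if n not in rec.sequences]
        if missing:
            raise TypingError(f"isolate {rec.isolate_id} missing loci {missing}")
        alleles = []
        for name in scheme.names:
            seq = rec.sequences[name]
            if trim:
                seq = trim_to_scheme(seq, scheme.get(name), min_identity)
            alleles.append(catalog.assign(name, seq))
        profiles.append(AllelicProfile(rec.isolate_id, tuple(alleles)))
    return profiles, assign_sts(profiles), catalog
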