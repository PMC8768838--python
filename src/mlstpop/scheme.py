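"""Six-locus MLST scheme for *Bifidobacterium longum*.

The scheme types isolates on trimmed internal fragments of six housekeeping
genes: *clpC* (ATP-dependent Clp protease ATP-binding subunit), *fusA*
(elongation factor G), *ileS* (isoleucyl-tRNA synthetase), *purF*
(amidophosphoribosyltransferase), *rplB* (50S ribosomal protein L2) and
*rpoB* (RNA polymerase beta subunit).  Canonical locus order is alphabetical.

Sequences are plain uppercase ``str`` over {A, C, G, T} at the API surface;
hot loops convert to small-integer numpy arrays via :func:`seq_to_array`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlphabetError, ConfigurationError

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

LOCUS_NAMES = ("clpC", "fusA", "ileS", "purF", "rplB", "rpoB")
LOCUS_LENGTHS = (600, 664, 487, 574, 355, 497)
CONCATENATED_LENGTH = sum(LOCUS_LENGTHS)  # 3177 bp


def seq_to_array(seq: str, *, context: str = "sequence") -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3).

    Case-insensitive.  Raises :class:`AlphabetError` naming the first bad
    position on any character outside the unambiguous DNA alphabet.
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODE[raw]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise AlphabetError(
            f"{context}: invalid character {seq[pos]!r} at position {pos} "
            "(only unambiguous A/C/G/T are accepted)"
        )
    return codes


def array_to_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class LocusDef:
    """One scheme locus: name, trimmed fragment length, codon frame offset
    (0/1/2, used only by dN/dS), and a reference allele used as the trimming
    anchor."""

    name: str
    trimmed_length: int
    frame_offset: int = 0
    reference_allele: str = ""

    def __post_init__(self) -> None:
        if self.trimmed_length <= 0:
            raise ConfigurationError(f"{self.name}: non-positive trimmed_length")
        if self.frame_offset not in (0, 1, 2):
            raise ConfigurationError(f"{self.name}: frame_offset must be 0, 1 or 2")
        if self.reference_allele:
            if len(self.reference_allele) != self.trimmed_length:
                raise ConfigurationError(
                    f"{self.name}: reference allele length "
                    f"{len(self.reference_allele)} != trimmed_length {self.trimmed_length}"
                )
            seq_to_array(self.reference_allele, context=f"{self.name} reference")


@dataclass(frozen=True)
class LocusScheme:
    """The ordered six-locus definition.

    Locus names are fixed to the B. longum scheme; trimmed lengths default to
    the published fragment lengths but are configurable (the simulator allows
    shorter loci for fast tests).
    """

    loci: tuple[LocusDef, ...]

    def __post_init__(self) -> None:
        names = tuple(l.name for l in self.loci)
        if names != LOCUS_NAMES:
            raise ConfigurationError(
                f"scheme loci must be exactly {LOCUS_NAMES} in order, got {names}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(l.trimmed_length for l in self.loci)

    @property
    def concatenated_length(self) -> int:
        return sum(self.lengths)

    def get(self, name: str) -> LocusDef:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def offsets(self) -> dict[str, tuple[int, int]]:
        """0-based half-open interval of each locus in the concatenation."""
        out: dict[str, tuple[int, int]] = {}
        start = 0
        for l in self.loci:
            out[l.name] = (start, start + l.trimmed_length)
            start += l.trimmed_length
        return out

    def concatenate(self, sequences: dict[str, str]) -> str:
        return "".join(sequences[n] for n in self.names)

    def split_concatenated(self, seq: str) -> dict[str, str]:
        if len(seq) != self.concatenated_length:
            raise ConfigurationError(
                f"concatenated length {len(seq)} != scheme length "
                f"{self.concatenated_length}"
            )
        return {n: seq[a:b] for n, (a, b) in self.offsets().items()}

    @classmethod
    def from_references(
        cls,
        references: dict[str, str],
        lengths: tuple[int, ...] | None = None,
        frame_offsets: dict[str, int] | None = None,
    ) -> "LocusScheme":
        """Build a scheme anchored on explicit reference alleles."""
        frame_offsets = frame_offsets or {}
        loci = []
        for i, name in enumerate(LOCUS_NAMES):
            ref = references[name].upper()
            length = lengths[i] if lengths is not None else len(ref)
            loci.append(
                LocusDef(name, length, frame_offsets.get(name, 0), ref)
            )
        return cls(tuple(loci))

    @classmethod
    def default(cls, seed: int = 240119) -> "LocusScheme":
        """The published locus lengths with synthetic reference alleles.

        The reference alleles are synthetic stand-ins: deterministic random
        sequences at the scheme's 62.5% GC, generated from a fixed seed.
        They anchor window trimming for simulated data; when typing real
        sequences, supply true references via :meth:`from_references`.
        """
        rng = np.random.default_rng(seed)
        refs: dict[str, str] = {}
        for name, length in zip(LOCUS_NAMES, LOCUS_LENGTHS):
            refs[name] = array_to_seq(random_sequence_codes(rng, length, 0.625))
        return cls.from_references(refs, LOCUS_LENGTHS)


def random_sequence_codes(
    rng: np.random.Generator, length: int, gc_target: float
) -> np.ndarray:
    """Draw i.i.d. base codes with P(G or C) = gc_target, uniform within
    the strong (G/C) and weak (A/T) classes."""
    p = np.array(
        [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    )
    return rng.choice(4, size=length, p=p).astype(np.uint8)
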