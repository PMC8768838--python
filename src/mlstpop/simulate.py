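"""Synthetic multi-lineage six-locus isolate datasets with known truth.

The generator emulates a bacterial population structured into a few deeply
diverged lineages (the three *B. longum* subspecies), with point mutation on
top of each lineage ancestor and rare donor-fragment homologous
recombination events of fixed length.  Every run returns the ground truth
(lineage labels, ancestors, implanted segments, realized mutation counts) so
downstream typing, clustering and recombination scanning can be scored
against a known answer.

Model
-----
* A latent root sequence is drawn i.i.d. per site with
  P(G or C) = ``gc_target``.
* Each lineage ancestor derives from the root by flipping each site
  independently with probability ``lineage_divergence / 2`` to a uniformly
  chosen different base, so any two lineage ancestors differ at a fraction
  of sites close to ``lineage_divergence`` (to first order) and the true
  lineage topology is a star: every lineage is monophyletic.  With a single
  lineage the ancestor is the root itself.
* Each isolate copies its lineage ancestor and substitutes each site
  independently with probability ``per_site_mutation_rate`` (uniform choice
  among the three other bases; Jukes–Cantor-like, no selection).
* With probability ``recombination_prob`` an isolate then receives one
  ``fragment_length``-bp fragment copied from a uniformly chosen *other*
  lineage's ancestor, at a uniform start position on the concatenation.

Coordinates are 0-based half-open on the concatenated sequence in canonical
locus order (clpC, fusA, ileS, purF, rplB, rpoB).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, MlstError
from .io import IsolateRecord
from .scheme import (
    LOCUS_LENGTHS,
    LOCUS_NAMES,
    LocusScheme,
    array_to_seq,
    random_sequence_codes,
    seq_to_array,
)

REGIONS = ("Xiangyang", "Enshi")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic population.

    Defaults: three lineages of 20 isolates each on the published locus
    lengths; per-site mutation rate 0.002, lineage divergence 0.02 per site,
    one 213-bp recombinant fragment per isolate with probability 0.02, and
    62.5% GC matching the concatenated scheme.
    """

    n_lineages: int = 3
    isolates_per_lineage: tuple[int, ...] | None = None
    per_site_mutation_rate: float = 0.002
    lineage_divergence: float = 0.02
    recombination_prob: float = 0.02
    fragment_length: int = 213
    gc_target: float = 0.625
    locus_lengths: tuple[int, ...] = LOCUS_LENGTHS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lineages < 1:
            raise ConfigurationError("n_lineages must be >= 1")
        if self.isolates_per_lineage is None:
            self.isolates_per_lineage = tuple([20] * self.n_lineages)
        self.isolates_per_lineage = tuple(int(x) for x in self.isolates_per_lineage)
        if len(self.isolates_per_lineage) != self.n_lineages:
            raise ConfigurationError(
                "isolates_per_lineage must have one entry per lineage"
            )
        if any(c <= 0 for c in self.isolates_per_lineage):
            raise ConfigurationError("isolate counts must be positive")
        for name in ("per_site_mutation_rate", "lineage_divergence",
                     "recombination_prob", "gc_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        self.locus_lengths = tuple(int(x) for x in self.locus_lengths)
        if len(self.locus_lengths) != 6 or any(x <= 0 for x in self.locus_lengths):
            raise ConfigurationError("locus_lengths must be six positive values")
        if not 0 <= self.fragment_length <= sum(self.locus_lengths):
            raise ConfigurationError(
                "fragment_length must lie in [0, concatenated length]"
            )

    @property
    def total_length(self) -> int:
        return sum(self.locus_lengths)

    @property
    def n_isolates(self) -> int:
        return sum(self.isolates_per_lineage)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class ImplantedSegment:
    """One recombination event: which isolate received which ancestral
    fragment, as a 0-based half-open concatenated-coordinate interval."""

    isolate_id: str
    start: int
    end: int
    donor_lineage: int


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset, for parameter-recovery tests."""

    lineage_of_isolate: dict[str, int]
    ancestral_sequences: dict[int, dict[str, str]]
    implanted_segments: list[ImplantedSegment]
    mutation_counts: dict[str, int]
    locus_lengths: tuple[int, ...] = LOCUS_LENGTHS

    def reference_scheme(self) -> LocusScheme:
        """Scheme anchored on the lineage-0 ancestral alleles."""
        return LocusScheme.from_references(
            self.ancestral_sequences[0], tuple(self.locus_lengths)
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lineage_of_isolate": self.lineage_of_isolate,
            "ancestral_sequences": {
                str(k): v for k, v in self.ancestral_sequences.items()
            },
            "implanted_segments": [asdict(s) for s in self.implanted_segments],
            "mutation_counts": self.mutation_counts,
            "locus_lengths": list(self.locus_lengths),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            lineage_of_isolate=d["lineage_of_isolate"],
            ancestral_sequences={
                int(k): v for k, v in d["ancestral_sequences"].items()
            },
            implanted_segments=[
                ImplantedSegment(**s) for s in d["implanted_segments"]
            ],
            mutation_counts=d["mutation_counts"],
            locus_lengths=tuple(d["locus_lengths"]),
        )


def _substitute(codes: np.ndarray, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace masked sites by a uniformly chosen *different* base."""
    out = codes.copy()
    k = int(mask.sum())
    if k:
        # offset 1..3 modulo 4 guarantees a different base
        out[mask] = (out[mask] + rng.integers(1, 4, size=k).astype(np.uint8)) % 4
    return out


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError(f"mutation rate {rate} outside [0, 1]")
    codes = seq_to_array(seq)
    mask = rng.random(codes.size) < rate
    return array_to_seq(_substitute(codes, mask, rng))


def implant_recombination(
    recipient_seq: str, donor_seq: str, start: int, length: int
) -> str:
    """Copy ``donor_seq[start:start+length]`` into the recipient."""
    if len(recipient_seq) != len(donor_seq):
        raise MlstError("recipient and donor must have equal length")
    if length < 0 or start < 0 or start + length > len(recipient_seq):
        raise MlstError(
            f"fragment [{start}, {start + length}) outside sequence of "
            f"length {len(recipient_seq)}"
        )
    return (
        recipient_seq[:start]
        + donor_seq[start : start + length]
        + recipient_seq[start + length :]
    )


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[IsolateRecord], SimulationTruth]:
    """Generate one dataset; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    L = config.total_length

    root = random_sequence_codes(rng, L, config.gc_target)
    if config.n_lineages == 1:
        ancestors = [root]
    else:
        ancestors = []
        for _ in range(config.n_lineages):
            mask = rng.random(L) < config.lineage_divergence / 2.0
            ancestors.append(_substitute(root, mask, rng))

    offsets = _locus_offsets(config.locus_lengths)
    records: list[IsolateRecord] = []
    lineage_of: dict[str, int] = {}
    segments: list[ImplantedSegment] = []
    mut_counts: dict[str, int] = {}

    idx = 0
    for lineage, count in enumerate(config.isolates_per_lineage):
        anc = ancestors[lineage]
        for _ in range(count):
            iso = f"iso{idx:04d}"
            idx += 1
            mask = rng.random(L) < config.per_site_mutation_rate
            codes = _substitute(anc, mask, rng)
            mut_counts[iso] = int((codes != anc).sum())
            if (
                config.n_lineages > 1
                and config.fragment_length > 0
                and rng.random() < config.recombination_prob
            ):
                others = [l for l in range(config.n_lineages) if l != lineage]
                donor = int(rng.choice(others))
                start = int(rng.integers(0, L - config.fragment_length + 1))
                end = start + config.fragment_length
                codes = codes.copy()
                codes[start:end] = ancestors[donor][start:end]
                segments.append(ImplantedSegment(iso, start, end, donor))
            concat = array_to_seq(codes)
            sequences = {n: concat[a:b] for n, (a, b) in offsets.items()}
            records.append(
                IsolateRecord(
                    iso,
                    region=REGIONS[int(rng.integers(0, len(REGIONS)))],
                    source="human stool",
                    sequences=sequences,
                )
            )
            lineage_of[iso] = lineage

    truth = SimulationTruth(
        lineage_of_isolate=lineage_of,
        ancestral_sequences={
            l: {n: array_to_seq(a[s:e]) for n, (s, e) in offsets.items()}
            for l, a in enumerate(ancestors)
        },
        implanted_segments=segments,
        mutation_counts=mut_counts,
        locus_lengths=config.locus_lengths,
    )
    return records, truth


def _locus_offsets(lengths: tuple[int, ...]) -> dict[str, tuple[int, int]]:
    out: dict[str, tuple[int, int]] = {}
    start = 0
    for name, length in zip(LOCUS_NAMES, lengths):
        out[name] = (start, start + length)
        start += length
    return out
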