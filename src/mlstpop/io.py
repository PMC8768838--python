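"""Readers and writers for every on-disk format the pipeline touches.

Conventions: FASTA headers are ``isolateID|locus``; tables are TSV, UTF-8,
Unix newlines (PubMLST style); trees are Newick.  Every writer round-trips
through its companion reader at the stated precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .errors import FormatError, TypingError
from .scheme import LOCUS_NAMES, LocusScheme, seq_to_array

log = logging.getLogger(__name__)


@dataclass
class IsolateRecord:
    """One isolate: id, provenance labels, and its per-locus sequences."""

    isolate_id: str
    region: str = ""
    source: str = ""
    sequences: dict[str, str] = field(default_factory=dict)

    def is_complete(self, scheme: LocusScheme) -> bool:
        return all(n in self.sequences for n in scheme.names)

    def concatenated(self, scheme: LocusScheme) -> str:
        return scheme.concatenate(self.sequences)


# ---------------------------------------------------------------- FASTA

def read_locus_fasta(
    path: str | Path, scheme: LocusScheme, locus: str | None = None
) -> list[IsolateRecord]:
    """Read a multi-FASTA of per-locus sequences into isolate records.

    Headers are ``isolateID|locus``; with ``locus=...`` a plain
    one-FASTA-per-locus layout (headers = isolate ids) is accepted instead.
    Records are merged by isolate id, in first-seen order; isolates missing
    loci are reported via logging and still returned (callers decide whether
    partial records are acceptable).
    """
    path = Path(path)
    records: dict[str, IsolateRecord] = {}
    seen: set[tuple[str, str]] = set()
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        if locus is None:
            if "|" not in rec.id:
                raise FormatError(
                    f"{path.name}: header {rec.id!r} lacks the "
                    "'isolateID|locus' separator"
                )
            isolate_id, locus_name = rec.id.split("|", 1)
        else:
            isolate_id, locus_name = rec.id, locus
        if locus_name not in scheme.names:
            raise FormatError(
                f"{path.name}: unknown locus {locus_name!r} in header {rec.id!r}"
            )
        if (isolate_id, locus_name) in seen:
            raise FormatError(
                f"{path.name}: duplicate record for isolate {isolate_id!r} "
                f"locus {locus_name!r}"
            )
        seen.add((isolate_id, locus_name))
        seq = str(rec.seq).upper()
        seq_to_array(seq, context=f"{path.name}:{rec.id}")
        records.setdefault(isolate_id, IsolateRecord(isolate_id)).sequences[
            locus_name
        ] = seq
    if n == 0:
        log.warning("%s: empty FASTA, no records read", path)
    for r in records.values():
        missing = [x for x in scheme.names if x not in r.sequences]
        if missing:
            log.warning("isolate %s missing loci: %s", r.isolate_id, missing)
    return list(records.values())


def write_locus_fasta(
    records: list[IsolateRecord], path: str | Path, width: int = 70
) -> None:
    """Write all per-locus sequences as one multi-FASTA (``id|locus``)."""
    out = []
    for r in records:
        for locus in LOCUS_NAMES:
            if locus in r.sequences:
                out.append(
                    SeqRecord(
                        Seq(r.sequences[locus]),
                        id=f"{r.isolate_id}|{locus}",
                        description="",
                    )
                )
    SeqIO.write(out, str(path), "fasta")


# ------------------------------------------------------------- metadata

def write_metadata_tsv(
    records: list[IsolateRecord],
    path: str | Path,
    lineage_of_isolate: dict[str, int] | None = None,
) -> None:
    rows = []
    for r in records:
        row = {"isolate": r.isolate_id, "region": r.region, "source": r.source}
        if lineage_of_isolate is not None:
            row["lineage"] = lineage_of_isolate[r.isolate_id]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"isolate": str})


# -------------------------------------------------------------- profiles

PROFILE_COLUMNS = ("isolate", "ST") + LOCUS_NAMES


def write_profiles_tsv(profiles, st_table, path: str | Path) -> None:
    """PubMLST-style profile table: ``isolate  ST  clpC ... rpoB``."""
    rows = []
    for p in profiles:
        if p.alleles is None or any(a < 1 for a in p.alleles):
            raise TypingError(f"isolate {p.isolate_id}: unassigned allele in profile")
        st = st_table.st_of(p)
        rows.append([p.isolate_id, st, *p.alleles])
    df = pd.DataFrame(rows, columns=list(PROFILE_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_profiles_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"isolate": str})
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: profile table missing columns {missing}")
    return df


# -------------------------------------------------------------- MST edges

def write_mst_edges(edges, st_table, path: str | Path) -> None:
    """Spanning-tree edge list: ``st_a  st_b  weight  isolates_a  isolates_b``."""
    rows = [
        {
            "st_a": e.st_a,
            "st_b": e.st_b,
            "weight": e.weight,
            "isolates_a": len(st_table.isolates_of(e.st_a)),
            "isolates_b": len(st_table.isolates_of(e.st_b)),
        }
        for e in edges
    ]
    pd.DataFrame(
        rows, columns=["st_a", "st_b", "weight", "isolates_a", "isolates_b"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_mst_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ----------------------------------------------------------------- stats

def write_stats_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")


# ---------------------------------------------------------------- Newick

def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a tree as Newick; support values ride as internal labels.

    Bootstrap percentages live both in ``node.support`` and ``node.name``;
    the serializer would emit them twice, so the copy written to disk keeps
    only the label.
    """
    out = tree.copy()
    for node in out.traverse():
        if hasattr(node, "support"):
            node.support = None
    out.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
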