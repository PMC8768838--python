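"""Clonal complexes, BURST groups and minimum spanning trees over allelic
profiles, following the goeBURST rules.

Groups are connected components of the graph linking ST pairs whose profiles
differ at no more than ``level`` loci (level 1 = single-locus variants,
giving clonal complexes; level 2 = double-locus variants, giving BURST
groups).  The founder of a group is the member maximizing the goeBURST
tie-break chain: most SLV neighbours, then most DLV neighbours, then highest
isolate frequency, then smallest ST number.  The spanning tree is built with
Kruskal's algorithm; because edge preference is fully specified by the
comparison chain below, the traversal order is immaterial to total weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import TypingError
from .mlst import STTable


@dataclass
class BurstGroup:
    level: int
    members: tuple[int, ...]
    founder: int
    variant_counts: dict[int, tuple[int, int, int]]  # ST -> (SLV, DLV, TLV)
    frequencies: dict[int, int]  # ST -> isolate count

    @property
    def n_sts(self) -> int:
        return len(self.members)

    @property
    def n_isolates(self) -> int:
        return sum(self.frequencies[st] for st in self.members)


@dataclass
class MstEdge:
    st_a: int
    st_b: int
    weight: int
    # comparison key that won this edge its slot, for audit:
    # (weight, -maxSLV, -maxDLV, -maxFreq, st_pair)
    tiebreak: tuple = field(default=(), compare=False)


def _profile_matrix(st_table: STTable) -> tuple[list[int], np.ndarray]:
    sts = st_table.sts
    mat = np.array([st_table.profile_of(st) for st in sts], dtype=np.int64)
    return sts, mat


def _distance_matrix(st_table: STTable) -> tuple[list[int], np.ndarray]:
    sts, mat = _profile_matrix(st_table)
    dist = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    return sts, dist


def all_variant_counts(st_table: STTable) -> dict[int, tuple[int, int, int]]:
    """(SLV, DLV, TLV) neighbour counts for every ST, within the whole
    dataset."""
    sts, dist = _distance_matrix(st_table)
    out: dict[int, tuple[int, int, int]] = {}
    for i, st in enumerate(sts):
        row = np.delete(dist[i], i)
        out[st] = (int((row == 1).sum()), int((row == 2).sum()), int((row == 3).sum()))
    return out


def variant_counts(st: int, st_table: STTable) -> tuple[int, int, int]:
    """SLV/DLV/TLV counts of one ST against every other ST in the table."""
    if st not in st_table.sts:
        raise TypingError(f"unknown ST {st}")
    return all_variant_counts(st_table)[st]


def _founder(members, counts, freqs) -> int:
    # most SLVs, then most DLVs, then highest frequency, then smallest ST id
    return max(members, key=lambda st: (counts[st][0], counts[st][1], freqs[st], -st))


def goeburst_groups(st_table: STTable, level: int = 1) -> list[BurstGroup]:
    """Partition STs into groups at the given variant-link threshold.

    ``level=1`` links SLV pairs (clonal complexes); ``level=2`` additionally
    links DLV pairs (BURST groups).  Singletons are returned as
    single-member groups.
    """
    if level not in (1, 2):
        raise ValueError("level must be 1 (SLV) or 2 (DLV)")
    sts, dist = _distance_matrix(st_table)
    counts = all_variant_counts(st_table)
    freqs = {st: len(st_table.isolates_of(st)) for st in sts}
    g = nx.Graph()
    g.add_nodes_from(sts)
    n = len(sts)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= level:
                g.add_edge(sts[i], sts[j])
    groups = []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp))
        groups.append(
            BurstGroup(
                level=level,
                members=members,
                founder=_founder(members, counts, freqs),
                variant_counts={st: counts[st] for st in members},
                frequencies={st: freqs[st] for st in members},
            )
        )
    # deterministic order: descending isolate count, then founder ST
    groups.sort(key=lambda grp: (-grp.n_isolates, grp.founder))
    return groups


def build_mst(st_table: STTable) -> list[MstEdge]:
    """Minimum spanning tree over STs under profile distance.

    Kruskal's algorithm over all ST pairs, ordered by the goeBURST edge
    comparison chain: lower weight first, then higher maximum endpoint SLV
    count, then DLV count, then higher maximum endpoint isolate frequency,
    then the lexicographically smallest ST number pair.  Output edge order
    follows acceptance order and is deterministic.
    """
    sts = st_table.sts
    if len(sts) <= 1:
        return []
    _, dist = _distance_matrix(st_table)
    counts = all_variant_counts(st_table)
    freqs = {st: len(st_table.isolates_of(st)) for st in sts}
    idx = {st: i for i, st in enumerate(sts)}

    def key(pair):
        a, b = pair
        return (
            int(dist[idx[a], idx[b]]),
            -max(counts[a][0], counts[b][0]),
            -max(counts[a][1], counts[b][1]),
            -max(freqs[a], freqs[b]),
            (min(a, b), max(a, b)),
        )

    pairs = [(a, b) for i, a in enumerate(sts) for b in sts[i + 1 :]]
    pairs.sort(key=key)

    parent = {st: st for st in sts}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[MstEdge] = []
    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            edges.append(
                MstEdge(a, b, int(dist[idx[a], idx[b]]), tiebreak=key((a, b)))
            )
            if len(edges) == len(sts) - 1:
                break
    return edges


def summarize_complexes(
    groups: list[BurstGroup], st_table: STTable
) -> tuple[pd.DataFrame, int]:
    """Tabulate multi-ST groups (one row each, descending isolate count) and
    report the singleton count.

    Group ids are CC1, CC2, ... for level-1 groups and BG1, BG2, ... for
    level-2 groups, in row order.
    """
    multi = [g for g in groups if g.n_sts >= 2]
    multi.sort(key=lambda g: (-g.n_isolates, g.founder))
    prefix = {1: "CC", 2: "BG"}
    rows = []
    for i, g in enumerate(multi, start=1):
        rows.append(
            {
                "group_id": f"{prefix[g.level]}{i}",
                "level": g.level,
                "founder": g.founder,
                "n_STs": g.n_sts,
                "n_isolates": g.n_isolates,
                "members": ",".join(str(st) for st in g.members),
            }
        )
    df = pd.DataFrame(
        rows, columns=["group_id", "level", "founder", "n_STs", "n_isolates", "members"]
    )
    n_singletons = sum(1 for g in groups if g.n_sts == 1)
    return df, n_singletons
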