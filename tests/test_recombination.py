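"""Site compatibility, the PHI-style permutation test, the segment scanner
and the simplified r/m estimator."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

import mlstpop as M
from mlstpop.errors import PhiTestError
from mlstpop.recombination import informative_site_positions

from conftest import SHORT_LENGTHS


# ------------------------------------------- brute-force tree compatibility

def _all_unrooted_trees(n_leaves):
    """All unrooted binary leaf-labeled trees as edge lists."""
    trees = [[(0, 100), (1, 100), (2, 100)]]
    for leaf in range(3, n_leaves):
        new_trees = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                w = 100 + leaf  # fresh internal id
                t = edges[:k] + edges[k + 1 :] + [(u, w), (v, w), (leaf, w)]
                new_trees.append(t)
        trees = new_trees
    return trees


def _fitch_changes(edges, states):
    """Minimum state changes of one character on a binary tree (Fitch sets,
    rooted along an arbitrary edge)."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    u0, v0 = edges[0]
    changes = 0

    def down(node, parent):
        nonlocal changes
        kids = [x for x in adj[node] if x != parent]
        if not kids:
            return {states[node]}
        sets = [down(k, node) for k in kids]
        inter = set.intersection(*sets)
        if inter:
            return inter
        changes += 1  # binary join with empty intersection
        return set.union(*sets)

    left = down(u0, v0)
    right = down(v0, u0)
    if not left & right:
        changes += 1
    return changes


def brute_two_site_compatible(col_i, col_j):
    """Exhaustive check: do the two characters fit some tree without
    homoplasy?  Duplicated joint states are collapsed first."""
    reps = sorted(set(zip(col_i, col_j)))
    k = len(reps)
    ci = [r[0] for r in reps]
    cj = [r[1] for r in reps]
    si, sj = len(set(ci)), len(set(cj))
    if k <= 3:
        return True  # any 3 taxa fit a star with no homoplasy for any character
    for edges in _all_unrooted_trees(k):
        if (
            _fitch_changes(edges, ci) == si - 1
            and _fitch_changes(edges, cj) == sj - 1
        ):
            return True
    return False


class TestSiteCompatibility:
    def test_three_joint_states_compatible(self):
        assert M.site_compatibility("AATT", "CCGG") is True

    def test_four_gametes_incompatible(self):
        assert M.site_compatibility("AATT", "CGCG") is False

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.choice(list("ACG"), size=6)
            b = rng.choice(list("ACG"), size=6)
            assert M.site_compatibility(a, b) == M.site_compatibility(b, a)

    def test_matches_exhaustive_tree_search_triallelic(self):
        rng = np.random.default_rng(1)
        checked_both = set()
        for _ in range(60):
            n = int(rng.integers(4, 7))
            a = rng.choice(list("ACG"), size=n)
            b = rng.choice(list("ACG"), size=n)
            got = M.site_compatibility(a, b)
            assert got == brute_two_site_compatible(a, b)
            checked_both.add(got)
        assert checked_both == {True, False}  # both outcomes exercised


class TestPhiTest:
    def test_compatible_sites_give_p_one(self):
        # two informative sites with identical split: compatible, statistic 0
        aln = ["AACCAA", "AACCAA", "TTGGAA", "TTGGAA"]
        r = M.phi_test(aln, w=100, n_permutations=50, seed=0)
        assert r.phi_statistic == 0.0
        assert r.p_value == 1.0

    def test_two_incompatible_sites_are_permutation_invariant(self):
        # exactly two informative, mutually incompatible adjacent sites
        aln = ["AC", "AG", "TC", "TG"]
        r = M.phi_test(aln, w=100, n_permutations=50, seed=0)
        assert r.phi_statistic == 1.0
        assert r.p_value == 1.0

    def test_insufficient_informative_sites(self):
        with pytest.raises(PhiTestError, match="insufficient"):
            M.phi_test(["AAAA", "AAAT", "AAAA", "AAAA"])

    def test_informative_site_definition(self):
        from mlstpop.scheme import seq_to_array

        aln = ["AAC", "AAC", "TAG", "TAG"]
        mat = np.vstack([seq_to_array(s) for s in aln])
        # column 0: 2+2 split (informative); column 1: constant;
        # column 2: 2+2 split (informative)
        assert list(informative_site_positions(mat)) == [0, 2]

    def test_sampled_p_matches_exhaustive_enumeration(self):
        # small alignment; enumerate all position permutations exactly
        rng = np.random.default_rng(5)
        aln = [
            "ACAAAAAAAAGTAAAAAAAC",
            "ACAAAAAAAAGTAAAAAAAC",
            "TGAAAAAAAACTAAAAAAGC",
            "TGAAAAAAAACGAAAAAAGA",
            "TTAAAAAAAACGAAAAAAGA",
            "TTAAAAAAAACGAAAAAAGC",
        ]
        from mlstpop.scheme import seq_to_array

        mat = np.vstack([seq_to_array(s) for s in aln])
        pos = informative_site_positions(mat)
        k = len(pos)
        assert 3 <= k <= 6
        w = 6
        cols = mat[:, pos]
        incomp = np.zeros((k, k), bool)
        for i, j in itertools.combinations(range(k), 2):
            bad = not M.site_compatibility(cols[:, i], cols[:, j])
            incomp[i, j] = incomp[j, i] = bad

        def stat(p):
            tot = cnt = 0
            for i, j in itertools.combinations(range(k), 2):
                if abs(p[i] - p[j]) <= w:
                    tot += incomp[i, j]
                    cnt += 1
            return tot / cnt if cnt else 0.0

        obs = stat(pos)
        perms = list(itertools.permutations(pos))
        exact = sum(stat(p) >= obs - 1e-12 for p in perms) / len(perms)
        r = M.phi_test(aln, w=w, n_permutations=4000, seed=1)
        assert r.phi_statistic == pytest.approx(obs)
        se = math.sqrt(exact * (1 - exact) / 4000)
        assert r.p_value == pytest.approx(exact, abs=max(4 * se, 0.01))


class TestSegmentScan:
    def _implanted_dataset(self, seed):
        rng = np.random.default_rng(seed)
        cfg = M.SimulationConfig(
            seed=seed, lineage_divergence=0.10, per_site_mutation_rate=0.002,
            recombination_prob=0.0,
        )
        records, truth = M.simulate_dataset(cfg)
        scheme = truth.reference_scheme()
        L = scheme.concatenated_length
        i = int(rng.integers(0, len(records)))
        rec = records[i]
        lin = truth.lineage_of_isolate[rec.isolate_id]
        donor = int(rng.choice([l for l in range(3) if l != lin]))
        start = int(rng.integers(0, L - 213 + 1))
        donor_seq = scheme.concatenate(truth.ancestral_sequences[donor])
        rec.sequences = scheme.split_concatenated(
            M.implant_recombination(rec.concatenated(scheme), donor_seq, start, 213)
        )
        return records, truth, scheme, rec.isolate_id, (start, start + 213)

    @staticmethod
    def _scan_by_lineage(records, truth, scheme, **kw):
        by_lin = {}
        for r in records:
            by_lin.setdefault(truth.lineage_of_isolate[r.isolate_id], []).append(r)
        out = []
        for recs in by_lin.values():
            seqs = [r.concatenated(scheme) for r in recs]
            out += M.scan_recombinant_segments(
                seqs, [r.isolate_id for r in recs], **kw
            )
        return out

    def test_recovers_implanted_fragment(self):
        hits = 0
        for seed in range(5):
            records, truth, scheme, iso, (a, b) = self._implanted_dataset(seed)
            segs = self._scan_by_lineage(records, truth, scheme)
            tset = set(range(a, b))
            for s in segs:
                if s.label == iso:
                    sset = set(range(s.start, s.end))
                    if len(tset & sset) / len(tset | sset) >= 0.5:
                        hits += 1
                        break
        assert hits >= 4

    def test_no_segments_without_recombination(self):
        for seed in range(5):
            cfg = M.SimulationConfig(
                seed=100 + seed, lineage_divergence=0.10,
                per_site_mutation_rate=0.002, recombination_prob=0.0,
            )
            records, truth = M.simulate_dataset(cfg)
            scheme = truth.reference_scheme()
            assert self._scan_by_lineage(records, truth, scheme) == []

    def test_window_larger_than_alignment(self):
        aln = ["ACGTACGT", "ACGTACGA", "ACGTACGT"]
        segs = M.scan_recombinant_segments(
            aln, ["x", "y", "y"], window_bp=10_000, score_cutoff=0.5
        )
        assert isinstance(segs, list)  # boundary contract: no crash

    def test_invariant_under_reordering_within_labels(self):
        records, truth, scheme, iso, _ = self._implanted_dataset(7)
        lin0 = [
            r for r in records if truth.lineage_of_isolate[r.isolate_id] == 0
        ]
        seqs = [r.concatenated(scheme) for r in lin0]
        labels = [r.isolate_id for r in lin0]
        fwd = M.scan_recombinant_segments(seqs, labels)
        rev = M.scan_recombinant_segments(seqs[::-1], labels[::-1])
        assert fwd == rev


class TestRmEstimate:
    def test_no_segments_gives_zero(self):
        rm = M.estimate_r_over_m(["AAAA", "AATA"], [])
        assert rm.r_over_m_simple == 0.0

    def test_all_snps_inside_gives_infinity(self):
        from mlstpop.recombination import RecombinantSegment

        seg = RecombinantSegment(0, 4, "x", 1, 0.25, 1e-9)
        rm = M.estimate_r_over_m(["AAAA", "AATA"], [seg])
        assert math.isinf(rm.r_over_m_simple)

    def test_ratio_increases_with_recombination_rate(self):
        rates, ratios = [], []
        for p_rec in (0.0, 0.2, 0.4, 0.6):
            for rep in range(4):
                cfg = M.SimulationConfig(
                    seed=int(1000 * p_rec) + rep, lineage_divergence=0.10,
                    per_site_mutation_rate=0.002, recombination_prob=p_rec,
                )
                records, truth = M.simulate_dataset(cfg)
                scheme = truth.reference_scheme()
                lin0 = [
                    r for r in records
                    if truth.lineage_of_isolate[r.isolate_id] == 0
                ]
                seqs = [r.concatenated(scheme) for r in lin0]
                segs = M.scan_recombinant_segments(
                    seqs, [r.isolate_id for r in lin0]
                )
                rm = M.estimate_r_over_m(seqs, segs)
                r = rm.r_over_m_simple
                rates.append(p_rec)
                ratios.append(r if not math.isinf(r) else 1e6)
        rho = sps.spearmanr(rates, ratios).statistic
        assert rho > 0
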