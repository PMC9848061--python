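"""Information and compositional-bias metrics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from orthosignal.infometrics import (
    chi2_homogeneity,
    compare_groups,
    compute_metrics,
    long_branch_scores,
    mean_bipartition_support,
    rcfv,
    saturation,
    significance_stars,
    site_counts,
    treeness_rcv,
    upper_decile_mean,
)
from orthosignal.matrix import Alignment
from orthosignal.treeio import parse_newick

from test_matrix import random_alignment


class TestSiteCounts:
    def test_definitions_on_three_columns(self):
        # columns AAAA / AAAC / AACC over four taxa
        aln = Alignment({"t1": "AAA", "t2": "AAA", "t3": "AAC", "t4": "ACC"})
        assert site_counts(aln) == (2, 1, 3)

    def test_all_constant(self):
        aln = Alignment({"a": "AAAA", "b": "AAAA"})
        assert site_counts(aln) == (0, 0, 4)

    def test_gaps_and_x_excluded_from_states(self):
        # -AXC column: only A and C count, each once -> variable, not informative
        aln = Alignment({"a": "-", "b": "A", "c": "X", "d": "C"})
        assert site_counts(aln) == (1, 0, 1)

    def test_matches_per_column_tally(self, rng):
        aln = random_alignment([f"T{i}" for i in range(12)], 100, rng, gap_p=0.2)
        var = inf = 0
        for j in range(aln.length):
            col = [aln[t][j] for t in aln.taxa if aln[t][j] not in "-X"]
            counts = {c: col.count(c) for c in set(col)}
            if len(counts) >= 2:
                var += 1
                if sum(1 for v in counts.values() if v >= 2) >= 2:
                    inf += 1
        assert site_counts(aln) == (var, inf, 100)


class TestTreenessRCV:
    def test_star_tree_treeness_zero(self):
        tree = parse_newick("(A:1,B:1,C:1,D:1);")
        aln = Alignment({t: "ACDE" for t in "ABCD"})
        treeness, _, _ = treeness_rcv(tree, aln)
        assert treeness == 0.0

    def test_identical_rows_rcv_zero_ratio_missing(self):
        tree = parse_newick("((A:1,B:1):1,C:1,D:1);")
        aln = Alignment({t: "ACDE" for t in "ABCD"})
        treeness, rcv, ratio = treeness_rcv(tree, aln)
        assert rcv == 0.0 and math.isnan(ratio)

    def test_hand_computed_four_taxon_case(self):
        # internal 3 / total 15; count deviations sum to 12 over 4 taxa x 4 sites
        tree = parse_newick("((A:1,B:2):3,C:4,D:5);")
        aln = Alignment({"A": "AAAA", "B": "AACC", "C": "CCCC", "D": "AAAA"})
        treeness, rcv, ratio = treeness_rcv(tree, aln)
        assert treeness == pytest.approx(3 / 15)
        assert rcv == pytest.approx(12 / 16)
        assert ratio == pytest.approx((3 / 15) / (12 / 16))

    def test_zero_length_tree_reported_missing(self):
        tree = parse_newick("((A:0,B:0):0,C:0,D:0);")
        aln = Alignment({t: "ACDE" for t in "ABCD"})
        assert math.isnan(treeness_rcv(tree, aln)[0])


class TestLongBranchScores:
    def test_balanced_tree_all_zero(self, quartet_tree):
        per, mean = long_branch_scores(quartet_tree)
        assert all(abs(v) < 1e-9 for v in per.values())
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_doubled_pendant_centering(self):
        tree = parse_newick("((A:2,B:1):1,(C:1,D:1):1);")
        per, mean = long_branch_scores(tree)
        assert per["A"] > 0
        assert all(per[t] < 0 for t in "BCD")
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert upper_decile_mean(per) == pytest.approx(per["A"])

    def test_matches_patristic_oracle(self, rng):
        from conftest import random_resolved_newick
        import dendropy

        newick = random_resolved_newick([f"T{i}" for i in range(8)], rng)
        tree = parse_newick(newick)
        per, _ = long_branch_scores(tree)
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = dtree.phylogenetic_distance_matrix()
        taxa = list(dtree.taxon_namespace)
        dists = {
            t.label: [pdm.patristic_distance(t, u) for u in taxa if u is not t]
            for t in taxa
        }
        grand = np.mean([d for v in dists.values() for d in v])
        for label, row in dists.items():
            assert per[label] == pytest.approx(100 * (np.mean(row) / grand - 1), rel=1e-6)


class TestSaturation:
    def test_identity_line(self):
        # all pairwise patristic distances 0.1; 3 of 30 columns all-distinct
        tree = parse_newick("(A:0.05,B:0.05,C:0.05);")
        base = "A" * 27
        aln = Alignment({"A": base + "CCC", "B": base + "DDD", "C": base + "EEE"})
        assert saturation(tree, aln) == pytest.approx(1.0)

    def test_half_slope(self):
        tree = parse_newick("(A:0.05,B:0.05,C:0.05);")
        base = "A" * 57
        aln = Alignment({"A": base + "CCC", "B": base + "DDD", "C": base + "EEE"})
        assert saturation(tree, aln) == pytest.approx(0.5)


class TestSupportAndComposition:
    def test_mean_support(self):
        tree = parse_newick("(((A,B)95,(C,D)80)62,(E,F)100,(G,H)100);")
        # supports 95, 80, 62, 100, 100
        assert mean_bipartition_support(tree) == pytest.approx((95 + 80 + 62 + 100 + 100) / 5)
        three = parse_newick("((A,B)95,((C,D)80,E)62,F);")
        assert mean_bipartition_support(three) == pytest.approx(79.0)

    def test_no_supports_missing(self):
        assert math.isnan(mean_bipartition_support(parse_newick("((A,B),C,D);")))

    def test_rcfv_identical_rows_zero(self):
        assert rcfv(Alignment({"a": "ACDE", "b": "ACDE"})) == 0.0

    def test_rcfv_two_single_state_taxa(self):
        # |1-0.5| per state per taxon: (0.5+0.5)+(0.5+0.5) over 2 taxa -> 1.0
        assert rcfv(Alignment({"a": "AAAA", "b": "CCCC"})) == pytest.approx(1.0)

    def test_rcfv_column_permutation_invariant(self, rng):
        aln = random_alignment(["a", "b", "c"], 30, rng)
        perm = rng.permutation(30)
        shuffled = Alignment({t: "".join(aln[t][j] for j in perm) for t in aln.taxa})
        assert rcfv(shuffled) == pytest.approx(rcfv(aln))

    def test_chi2_identical_rows(self):
        stat, df, p = chi2_homogeneity(Alignment({"a": "ACAC", "b": "ACAC"}))
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_chi2_textbook_two_by_two(self):
        aln = Alignment({"t1": "A" * 90 + "C" * 10, "t2": "A" * 10 + "C" * 90})
        stat, df, p = chi2_homogeneity(aln)
        # sum (o-e)^2/e with all expected counts 50: 4 * 1600/50
        assert stat == pytest.approx(128.0)
        assert df == 1

    def test_chi2_taxon_order_invariant(self, rng):
        aln = random_alignment(["a", "b", "c", "d"], 50, rng)
        rev = Alignment({t: aln[t] for t in reversed(aln.taxa)})
        assert chi2_homogeneity(aln)[0] == pytest.approx(chi2_homogeneity(rev)[0])

    def test_degenerate_single_state_missing(self):
        stat, df, p = chi2_homogeneity(Alignment({"a": "AAAA", "b": "AAAA"}))
        assert math.isnan(stat)


class TestCompareGroups:
    def _metrics(self, values, rng):
        out = []
        for v in values:
            tree = parse_newick(f"((A:{v},B:1):1,C:1,D:1);")
            aln = random_alignment(list("ABCD"), 20, rng)
            m = compute_metrics(aln, tree)
            out.append(m)
        return out

    def test_identical_groups_not_significant(self, rng):
        group = self._metrics(np.linspace(0.5, 2, 12), rng)
        result = compare_groups(group, group)
        assert (result.p_value > 0.05).all()

    def test_shifted_metric_detected(self, rng):
        a = self._metrics(rng.uniform(0.5, 1.0, size=50), rng)
        b = self._metrics(rng.uniform(0.5, 1.0, size=50) + 50.0, rng)
        result = compare_groups(a, b).set_index("metric")
        assert result.loc["treeness", "p_value"] < 0.0001
        assert result.loc["treeness", "stars"] == "****"

    def test_pvalues_match_permutation_oracle(self, rng):
        a = list(rng.normal(0, 1, size=10))
        b = list(rng.normal(1, 1, size=10))
        _, p_ref = sps.mannwhitneyu(a, b, alternative="two-sided")
        pooled = np.array(a + b)
        obs = sps.rankdata(pooled)[:10].sum()
        n_perm = 10000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            s = sps.rankdata(perm)[:10].sum()
            if abs(s - 105.0) >= abs(obs - 105.0) - 1e-9:  # 105 = null mean rank sum
                count += 1
        p_perm = count / n_perm
        assert p_perm == pytest.approx(p_ref, abs=0.03)

    def test_star_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.2) == "ns"
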