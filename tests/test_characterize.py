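import numpy as np
import pytest

from spongescore import (
    BipartiteNetwork,
    GeneSet,
    NSRProfile,
    TargetClass,
    assign_groups,
    classify_lmc,
    compare_distributions,
    compute_auc,
    functional_fraction,
    mean_auc,
    proportion_trend_test,
    rank_correlation,
)

from test_de import make_expr


def _net(mirnas, cls=TargetClass.MRNA):
    return BipartiteNetwork.from_edges([(m, f"t-{m}") for m in mirnas], cls)


class TestClassifyLMC:
    def test_intersection(self):
        assert classify_lmc(_net("AB"), _net("BC", TargetClass.LNCRNA)) == {"B"}

    def test_disjoint_and_identical(self):
        assert classify_lmc(_net("AB"), _net("CD", TargetClass.LNCRNA)) == set()
        assert classify_lmc(_net("AB"), _net("AB", TargetClass.LNCRNA)) == {"A", "B"}

    def test_symmetric(self):
        a, b = _net("ABC"), _net("BCD", TargetClass.LNCRNA)
        assert classify_lmc(a, b) == {"B", "C"}
        assert classify_lmc(a, b) == frozenset(b.mirnas & a.mirnas)


class TestAssignGroups:
    @pytest.mark.parametrize(
        "nsr_m,nsr_l,group",
        [(0, 0, "I"), (3, 0, "II"), (0, 2, "II"), (1, 1, "III")],
    )
    def test_definition_cases(self, nsr_m, nsr_l, group):
        (c,) = assign_groups([NSRProfile("m", nsr_m, nsr_l, nsr_m + nsr_l)])
        assert c.group == group

    def test_partition_exhaustive_exclusive(self):
        rng = np.random.default_rng(13)
        profiles = [
            NSRProfile(f"m{i}", int(a), int(b), int(a + b))
            for i, (a, b) in enumerate(rng.integers(0, 4, (40, 2)))
        ]
        groups = assign_groups(profiles)
        counts = {g: sum(1 for c in groups if c.group == g) for g in "I II III".split()}
        assert sum(counts.values()) == len(profiles)


class TestCompareDistributions:
    def test_identical_samples(self):
        d, p = compare_distributions([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = compare_distributions([0, 0, 0], [1, 1, 1])
        assert d == 1.0

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(19)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            _, p = compare_distributions(rng.normal(size=50), rng.normal(size=50))
            rejections += p < 0.05
        assert rejections / n_rep < 0.12  # near nominal 5%

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])


class TestProportionTrendTest:
    def test_identical_proportions_chi2_zero(self):
        chi2, p = proportion_trend_test({"I": (5, 10), "II": (5, 10)})
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_two_by_two_hand_value(self):
        # [[10,0],[0,10]]: every expected cell is 5, sum (O-E)^2/E = 20
        chi2, _ = proportion_trend_test({"a": (10, 10), "b": (0, 10)})
        assert chi2 == pytest.approx(20.0)

    def test_three_identical_groups(self):
        chi2, _ = proportion_trend_test(
            {"I": (2, 10), "II": (4, 20), "III": (6, 30)}
        )
        assert chi2 == pytest.approx(0.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            proportion_trend_test({"a": (1, 2), "b": (0, 0)})


class TestRankCorrelation:
    def test_monotone_and_reversed(self):
        x = [1, 2, 3, 4, 5]
        assert rank_correlation(x, [2, 4, 8, 16, 32])[0] == pytest.approx(1.0)
        assert rank_correlation(x, [5, 4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(23)
        rho, _ = rank_correlation(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(rho) < 0.1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rank_correlation([1, 2, 3], [1, 2])


class TestFunctionalFraction:
    GS = GeneSet("tf", frozenset({"G1"}))

    def test_half_overlap(self):
        out = functional_fraction({"m": {"G1", "G2"}}, self.GS)
        assert out["all"] == pytest.approx(0.5)

    def test_disjoint_and_superset(self):
        assert functional_fraction({"m": {"G9"}}, self.GS)["all"] == 0.0
        assert functional_fraction({"m": {"G1"}}, self.GS)["all"] == 1.0

    def test_union_vs_per_mirna_mean(self):
        targets = {"a": {"G1"}, "b": {"G2", "G3"}}
        classes = {"a": "lmc", "b": "lmc"}
        union = functional_fraction(targets, self.GS, classes, "union")
        mean = functional_fraction(targets, self.GS, classes, "per_mirna_mean")
        assert union["lmc"] == pytest.approx(1 / 3)
        assert mean["lmc"] == pytest.approx(0.5)  # (1 + 0)/2

    def test_empty_union_reported_missing(self):
        out = functional_fraction({"m": set()}, self.GS)
        assert out["all"] is None


class TestComputeAUC:
    def test_perfect_separation(self):
        expr = make_expr([[1, 2, 3, 4, 5, 6]], 3, 3)
        res = compute_auc(expr, "f0")
        assert res.auc == 1.0 and res.direction == "up_in_case"

    def test_interleaved_three_quarters(self):
        expr = make_expr([[1, 3, 2, 4]], 2, 2)
        assert compute_auc(expr, "f0").auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        expr = make_expr([[2.0] * 6], 3, 3)
        assert compute_auc(expr, "f0").auc == pytest.approx(0.5)

    def test_auto_orientation_flips_down_regulation(self):
        expr = make_expr([[4, 5, 6, 1, 2, 3]], 3, 3)
        res = compute_auc(expr, "f0", "auto")
        assert res.auc == 1.0 and res.direction == "down_in_case"

    def test_fixed_orientation_uses_fold_change_sign(self):
        expr = make_expr([[4, 5, 6, 1, 2, 3]], 3, 3)
        res = compute_auc(expr, "f0", "fixed")
        assert res.direction == "down_in_case" and res.auc == 1.0

    def test_brute_force_pair_counting(self):
        rng = np.random.default_rng(29)
        for _ in range(30):
            n1, n2 = rng.integers(2, 8), rng.integers(2, 8)
            vals = rng.integers(0, 5, n1 + n2).astype(float)  # ties likely
            expr = make_expr([vals], int(n1), int(n2))
            ref, case = vals[:n1], vals[n1:]
            conc = sum(
                1.0 if c > r else (0.5 if c == r else 0.0)
                for c in case
                for r in ref
            ) / (n1 * n2)
            expected = max(conc, 1 - conc)
            assert compute_auc(expr, "f0").auc == pytest.approx(expected)


class TestMeanAUC:
    def test_simple_mean_and_single(self):
        assert mean_auc([0.5, 1.0]) == pytest.approx(0.75)
        assert mean_auc([0.8707]) == pytest.approx(0.8707)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_auc([])
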