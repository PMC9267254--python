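import itertools

import numpy as np
import pytest
from scipy import stats

from spongescore import (
    CeRNANetwork,
    NSRProfile,
    compute_nsr,
    extract_condition_specific,
    nsr_significance,
    select_candidates,
    signed_rank_greater_p,
)


def net(*triplets):
    return CeRNANetwork(triplets=frozenset(triplets))


class TestExtractConditionSpecific:
    def test_keeps_de_mirna_and_de_mrna_triplets(self):
        g = net(("L1", "A", "G1"), ("L1", "B", "G2"))
        s = extract_condition_specific(g, {"A"}, {"G1"})
        assert s.triplets == {("L1", "A", "G1")}

    def test_empty_de_sets_warn_and_empty(self):
        g = net(("L1", "A", "G1"))
        with pytest.warns(UserWarning, match="empty"):
            s = extract_condition_specific(g, set(), set())
        assert len(s) == 0

    def test_full_de_sets_identity(self):
        g = net(("L1", "A", "G1"), ("L2", "B", "G2"))
        s = extract_condition_specific(g, {"A", "B"}, {"G1", "G2"})
        assert s.triplets == g.triplets

    def test_lncrnas_not_filtered(self):
        g = net(("L9", "A", "G1"))
        s = extract_condition_specific(g, {"A"}, {"G1"})
        assert s.lncrnas == {"L9"}  # survives without any DE evidence


class TestComputeNSR:
    def test_hand_projection_shared_mrna(self):
        # mRNA projection: single edge (A,G1); lncRNA projection: L1,L2 both
        # exclusive to A
        profiles = compute_nsr(net(("L1", "A", "G1"), ("L2", "A", "G1")))
        (p,) = profiles
        assert (p.nsr_mrna, p.nsr_lncrna, p.nsr_sponge) == (1, 2, 3)

    def test_shared_partners_zero_everywhere(self):
        profiles = compute_nsr(net(("L1", "A", "G1"), ("L1", "B", "G1")))
        assert {(p.nsr_mrna, p.nsr_lncrna) for p in profiles} == {(0, 0)}

    def test_additivity_and_degree1_sum_identity(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            trips = {
                (f"L{rng.integers(4)}", f"m{rng.integers(5)}", f"G{rng.integers(6)}")
                for _ in range(rng.integers(1, 25))
            }
            network = net(*trips)
            profiles = compute_nsr(network)
            for p in profiles:
                assert p.nsr_sponge == p.nsr_mrna + p.nsr_lncrna
            proj = network.mrna_projection()
            n_deg1 = sum(1 for t in proj.targets if proj.degree(t, "target") == 1)
            assert sum(p.nsr_mrna for p in profiles) == n_deg1

    def test_second_edge_steals_single_line(self):
        before = {
            p.mirna_id: p.nsr_mrna
            for p in compute_nsr(net(("L1", "A", "G1"), ("L2", "B", "G2")))
        }
        after = {
            p.mirna_id: p.nsr_mrna
            for p in compute_nsr(
                net(("L1", "A", "G1"), ("L2", "B", "G2"), ("L2", "B", "G1"))
            )
        }
        assert before["A"] - after["A"] == 1  # A loses exactly one (G1 shared now)
        assert after["B"] == before["B"]  # B still owns G2; G1 belongs to no one

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            compute_nsr(net())


class TestSignedRank:
    def test_exact_four_positive_differences(self):
        # [5,1,1,1,1]: four +4 differences; P(all signs positive) = 1/16
        assert signed_rank_greater_p([4, 4, 4, 4]) == pytest.approx(1 / 16)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(4, 15))
            d = rng.normal(0.3, 1.0, n)
            d = d[d != 0]
            if len(np.unique(np.abs(d))) != len(d):
                continue  # scipy's exact path requires untied |d|
            expected = stats.wilcoxon(d, alternative="greater", method="exact").pvalue
            assert signed_rank_greater_p(d) == pytest.approx(expected, rel=1e-9)

    def test_sign_flip_enumeration_oracle(self):
        # exhaustively enumerate all 2^n sign assignments
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            d = np.round(rng.normal(0.5, 1.0, n), 1)
            d = d[d != 0]
            if d.size == 0:
                continue
            ranks = stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            count = sum(
                1
                for signs in itertools.product([0, 1], repeat=d.size)
                if ranks[np.array(signs, bool)].sum() >= w_obs - 1e-9
            )
            assert signed_rank_greater_p(d) == pytest.approx(
                count / 2 ** d.size, rel=1e-9
            )

    def test_normal_approximation_above_limit(self):
        d = np.concatenate([np.full(30, 2.0), np.full(10, -1.0)])
        p = signed_rank_greater_p(d)
        assert 0 < p < 0.01  # strongly positive median

    def test_all_zero_differences(self):
        assert signed_rank_greater_p([0.0, 0.0]) == 1.0


def profiles_from_scores(scores):
    return [
        NSRProfile(f"m{i}", s, 0, s) for i, s in enumerate(scores)
    ]


class TestNSRSignificance:
    def test_top_scorer_exact_p(self):
        profiles = nsr_significance(profiles_from_scores([5, 1, 1, 1, 1]), "mrna")
        assert profiles[0].p_mrna == pytest.approx(1 / 16)

    def test_minimum_scorer_never_significant(self):
        for method in ("signed_rank", "empirical"):
            profiles = nsr_significance(
                profiles_from_scores([5, 3, 2, 2, 1]), "mrna", method
            )
            assert profiles[-1].p_mrna >= 0.5

    def test_all_equal_all_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            profiles = nsr_significance(profiles_from_scores([2, 2, 2]), "mrna")
        assert all(p.p_mrna == 1.0 for p in profiles)

    def test_empirical_formula(self):
        profiles = nsr_significance(
            profiles_from_scores([5, 3, 1, 1]), "mrna", "empirical"
        )
        # p = (1 + #{others >= own}) / n_mirnas
        assert profiles[0].p_mrna == pytest.approx(1 / 4)
        assert profiles[1].p_mrna == pytest.approx(2 / 4)
        assert profiles[2].p_mrna == pytest.approx(4 / 4)  # tied minimum

    def test_methods_agree_on_ranking_without_ties(self):
        scores = [9, 7, 5, 3, 2, 1]
        by = {}
        for method in ("signed_rank", "empirical"):
            profs = nsr_significance(profiles_from_scores(scores), "mrna", method)
            by[method] = stats.rankdata([p.p_mrna for p in profs])
        rho = stats.spearmanr(by["signed_rank"], by["empirical"]).statistic
        assert rho == pytest.approx(1.0)

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            nsr_significance(profiles_from_scores([1, 2]), "mrna")


class TestSelectCandidates:
    def _profile(self, name, sponge, ps):
        return NSRProfile(name, sponge, 0, sponge,
                          p_mrna=ps[0], p_lncrna=ps[1], p_sponge=ps[2])

    def test_conjunction_required(self):
        yes = self._profile("a", 5, (0.01, 0.04, 0.02))
        no = self._profile("b", 4, (0.01, 0.06, 0.02))
        out = select_candidates([yes, no], alpha=0.05)
        assert [p.is_candidate for p in out] == [True, False]

    def test_sorted_by_sponge_then_id(self):
        out = select_candidates(
            [
                self._profile("b", 3, (1, 1, 1)),
                self._profile("a", 3, (1, 1, 1)),
                self._profile("c", 9, (1, 1, 1)),
            ],
            alpha=0.05,
        )
        assert [p.mirna_id for p in out] == ["c", "a", "b"]

    def test_missing_p_rejected(self):
        with pytest.raises(ValueError, match="not filled"):
            select_candidates([NSRProfile("a", 1, 0, 1)], alpha=0.05)

    def test_empty_input(self):
        assert select_candidates([], alpha=0.05) == []


class TestNSRProfileInvariants:
    def test_additivity_enforced(self):
        with pytest.raises(ValueError, match="nsr_sponge"):
            NSRProfile("a", 2, 3, 6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            NSRProfile("a", -1, 1, 0)
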