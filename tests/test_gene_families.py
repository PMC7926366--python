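"""Birth-death gene-family model: transition law, likelihood, estimation,
p-values, branch calls, convergence screening, summaries."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg
from scipy.stats import kstest

from amphisel.gene_families import (
    BirthDeathParams,
    FamilyTestResult,
    bd_generator,
    bd_transition_matrix,
    bd_transition_prob,
    branch_changes,
    convergent_contractions,
    estimate_lambda,
    family_log_likelihood,
    family_pvalues,
    group_count_summary,
    rapid_branch_summary,
)
from amphisel.io_core import parse_labeled_tree
from amphisel.synthetic_data import (
    default_time_tree,
    simulate_family_matrix,
)


class TestTransitionProb:
    def test_identity_at_zero_time(self):
        for s in range(5):
            for c in range(5):
                expected = 1.0 if c == s else 0.0
                assert bd_transition_prob(s, c, 0.01, 0.0) == expected

    def test_extinction_from_one_is_alpha(self):
        lam, t = 0.002, 110.0
        alpha = lam * t / (1 + lam * t)
        assert bd_transition_prob(1, 0, lam, t) == pytest.approx(alpha)

    def test_zero_is_absorbing(self):
        assert bd_transition_prob(0, 0, 0.01, 50.0) == 1.0
        assert bd_transition_prob(0, 3, 0.01, 50.0) == 0.0

    @pytest.mark.parametrize("s,lam,t", [(1, 0.002, 100), (5, 0.005, 200),
                                         (12, 0.01, 50)])
    def test_rows_normalize_with_large_truncation(self, s, lam, t):
        cmax = 400
        p = np.array([bd_transition_prob(s, c, lam, t) for c in range(cmax)])
        assert p.sum() == pytest.approx(1.0, abs=1e-8)

    def test_matrix_matches_expm_oracle(self):
        lam, t, cmax = 0.003, 120.0, 30
        p = bd_transition_matrix(lam, t, cmax)
        g = bd_generator(lam, 80)
        p_oracle = scipy.linalg.expm(g * t)[: cmax + 1, : cmax + 1]
        assert np.abs(p[:15, :15] - p_oracle[:15, :15]).max() < 1e-6

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            bd_transition_prob(-1, 0, 0.01, 1.0)
        with pytest.raises(ValueError):
            bd_transition_prob(1, 0, 0.01, -1.0)


class TestFamilyLikelihood:
    def test_single_branch_composition_base_case(self):
        """On a two-leaf star with one informative leaf, the likelihood is a
        root-prior average of transition probabilities."""
        tree = parse_labeled_tree("(A:100,B:0);")
        params = BirthDeathParams(lambda_=0.002)
        cmax = 20
        ll = family_log_likelihood(
            {"A": 3, "B": 5}, tree, params, cmax=cmax,
            root_prior=np.r_[0.0, np.ones(cmax) / cmax],
        )
        # B:0 pins the root at 5; A evolves for 100 My
        expected = np.log(
            (1.0 / cmax) * bd_transition_prob(5, 3, 0.002, 100.0)
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_three_leaf_enumeration_oracle(self):
        tree = parse_labeled_tree("((A:50,B:80):40,C:90);")
        params = BirthDeathParams(lambda_=0.004)
        cmax = 12
        counts = {"A": 2, "B": 4, "C": 3}
        ll = family_log_likelihood(counts, tree, params, cmax=cmax)
        # exhaustive sum over root and internal-node counts
        total = 0.0
        for root in range(1, cmax + 1):
            for anc in range(cmax + 1):
                total += (
                    (1.0 / cmax)
                    * bd_transition_prob(root, anc, 0.004, 40.0)
                    * bd_transition_prob(anc, 2, 0.004, 50.0)
                    * bd_transition_prob(anc, 4, 0.004, 80.0)
                    * bd_transition_prob(root, 3, 0.004, 90.0)
                )
        assert ll == pytest.approx(np.log(total), abs=1e-10)

    def test_outlier_lowers_likelihood(self):
        tree = default_time_tree()
        params = BirthDeathParams(lambda_=0.002)
        leaves = tree.leaves()
        typical = {sp: 5 for sp in leaves}
        outlier = dict(typical, mudskipper=40)
        cmax = 90
        ll_typ = family_log_likelihood(typical, tree, params, cmax=cmax)
        ll_out = family_log_likelihood(outlier, tree, params, cmax=cmax)
        assert ll_out < ll_typ

    def test_leaf_order_invariance(self):
        tree = default_time_tree()
        params = BirthDeathParams(lambda_=0.003)
        counts = {sp: k % 4 + 1 for k, sp in enumerate(tree.leaves())}
        ll1 = family_log_likelihood(counts, tree, params)
        shuffled = dict(reversed(list(counts.items())))
        ll2 = family_log_likelihood(shuffled, tree, params)
        assert ll1 == pytest.approx(ll2, abs=1e-12)

    def test_truncation_below_observed_rejected(self):
        tree = parse_labeled_tree("(A:10,B:10);")
        with pytest.raises(ValueError, match="truncation"):
            family_log_likelihood(
                {"A": 30, "B": 1}, tree, BirthDeathParams(0.01), cmax=10
            )


class TestEstimateLambda:
    def test_recovery_within_30_percent(self, family_recovery):
        lam_hat = family_recovery["lambda_hat"]
        true = family_recovery["true_lambda"]
        assert abs(lam_hat - true) / true < 0.30

    def test_constant_matrix_hits_lower_bound(self):
        tree = default_time_tree()
        matrix = pd.DataFrame(
            {sp: [3] * 20 for sp in tree.leaves()},
            index=[f"f{i}" for i in range(20)],
        )
        params = estimate_lambda(matrix, tree)
        assert params.at_lower_bound

    def test_time_rescaling_halves_lambda(self):
        """lambda*t identifiability: doubling branch times halves lambda."""
        tree = default_time_tree()
        matrix, _ = simulate_family_matrix(
            tree, 0.002, n_families=150, seed=77
        )
        lam1 = estimate_lambda(tree=tree, matrix=matrix,
                               root_prior_range=(1, 10)).lambda_
        lam2 = estimate_lambda(tree=tree.scaled(2.0), matrix=matrix,
                               root_prior_range=(1, 10)).lambda_
        assert lam2 == pytest.approx(lam1 / 2, rel=0.05)

    def test_too_few_families_rejected(self):
        tree = parse_labeled_tree("(A:10,B:10);")
        matrix = pd.DataFrame({"A": [1], "B": [2]}, index=["f1"])
        with pytest.raises(ValueError, match="2 families"):
            estimate_lambda(matrix, tree)


class TestPvalues:
    def test_add_one_floor(self, family_recovery):
        for rep in family_recovery["replicates"]:
            assert rep["planted_p"] >= 1.0 / 1001.0

    def test_planted_contraction_detected(self, family_recovery):
        """10-fold contraction on the mudskipper branch yields p < 0.05."""
        detected = [r["planted_p"] < 0.05 for r in family_recovery["replicates"]]
        assert np.mean(detected) >= 0.9

    def test_null_pvalues_approximately_uniform(self):
        tree = default_time_tree()
        cmax_range = (1, 10)
        matrix, _ = simulate_family_matrix(
            tree, 0.002, n_families=500, root_range=cmax_range, seed=88
        )
        params = estimate_lambda(matrix, tree, root_prior_range=cmax_range)
        pv = family_pvalues(
            matrix, tree, params, n_sim=800, seed=2,
            root_prior_range=cmax_range,
        )
        assert kstest(pv, "uniform").statistic < 0.1

    def test_small_nsim_warns(self):
        tree = parse_labeled_tree("(A:10,B:10);")
        matrix = pd.DataFrame({"A": [2, 3], "B": [2, 4]}, index=["f1", "f2"])
        params = BirthDeathParams(lambda_=0.01)
        with np.errstate(all="ignore"):
            pv = family_pvalues(matrix, tree, params, n_sim=50, seed=0)
        assert ((pv > 0) & (pv <= 1)).all()


class TestBranchChanges:
    def test_constant_family_all_none(self):
        tree = default_time_tree()
        counts = {sp: 4 for sp in tree.leaves()}
        calls, anc = branch_changes(
            counts, tree, BirthDeathParams(0.002), root_prior_range=(1, 10)
        )
        assert set(calls.values()) == {"none"}
        assert set(anc.values()) == {4}

    def test_planted_contraction_called(self, family_recovery):
        calls = [r["planted_call"] for r in family_recovery["replicates"]]
        frac = np.mean([c == "contraction" for c in calls])
        assert frac >= 0.9

    def test_calls_independent_of_family_id(self):
        tree = default_time_tree()
        counts = {sp: (3 if sp != "mudskipper" else 1) for sp in tree.leaves()}
        p = BirthDeathParams(0.001)
        c1, _ = branch_changes(counts, tree, p, root_prior_range=(2, 5))
        c2, _ = branch_changes(dict(counts), tree, p, root_prior_range=(2, 5))
        assert c1 == c2


class TestConvergenceAndSummaries:
    def _result(self, fam, p, calls):
        return FamilyTestResult(
            family_id=fam, lnL=-10.0, p_value=p, branch_calls=calls,
            ancestral_counts={},
        )

    def test_toy_convergent_set(self):
        base = {"mudskipper": "none", "Tetrapoda": "none"}
        results = [
            self._result("f1", 0.01, {"mudskipper": "contraction",
                                      "Tetrapoda": "contraction"}),
            self._result("f2", 0.02, {"mudskipper": "contraction",
                                      "Tetrapoda": "contraction"}),
            self._result("f3", 0.01, {"mudskipper": "contraction",
                                      "Tetrapoda": "none"}),
            self._result("f4", 0.50, {"mudskipper": "contraction",
                                      "Tetrapoda": "contraction"}),
        ]
        out = convergent_contractions(results, "mudskipper", "Tetrapoda")
        assert out == {"f1", "f2"}

    def test_empty_results(self):
        assert convergent_contractions([], "a", "b") == set()

    def test_unknown_branch_rejected(self):
        results = [self._result("f1", 0.01, {"x": "none"})]
        with pytest.raises(ValueError, match="unknown branch"):
            convergent_contractions(results, "x", "nope")

    def test_rapid_branch_summary_counts(self):
        results = [
            self._result("f1", 0.01, {"b1": "expansion", "b2": "none"}),
            self._result("f2", 0.01, {"b1": "contraction", "b2": "none"}),
            self._result("f3", 0.90, {"b1": "expansion", "b2": "expansion"}),
        ]
        df = rapid_branch_summary(results)
        assert df.loc["b1", "expansion"] == 1
        assert df.loc["b1", "contraction"] == 1
        assert "b2" not in df.index

    def test_group_summary_arithmetic(self):
        matrix = pd.DataFrame(
            {"s1": [20, 29], "s2": [25, 25], "s3": [26, 25], "s4": [24, 25]},
            index=["f1", "f2"],
        )
        out = group_count_summary(
            matrix, ["f1", "f2"],
            {"aquatic": ["s1", "s2", "s3", "s4"]},
        )
        assert out.loc["s1", "total"] == 49
        assert out.loc["s1", "group_mean"] == pytest.approx(49.75)

    def test_single_species_group(self):
        matrix = pd.DataFrame({"s1": [3], "s2": [9]}, index=["f1"])
        out = group_count_summary(matrix, ["f1"], {"solo": ["s2"]})
        assert out.loc["s2", "group_mean"] == 9

    def test_totals_match_column_sum_oracle(self):
        rng = np.random.default_rng(6)
        matrix = pd.DataFrame(
            rng.integers(0, 10, size=(30, 4)),
            columns=list("abcd"), index=[f"f{i}" for i in range(30)],
        )
        subset = [f"f{i}" for i in range(0, 30, 2)]
        out = group_count_summary(matrix, subset, {"g": list("abcd")})
        for sp in "abcd":
            assert out.loc[sp, "total"] == matrix.loc[subset, sp].sum()

    def test_empty_group_rejected(self):
        matrix = pd.DataFrame({"s1": [1]}, index=["f1"])
        with pytest.raises(ValueError, match="empty"):
            group_count_summary(matrix, ["f1"], {"g": []})
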