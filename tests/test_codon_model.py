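"""Codon model: F3x4, rate matrix, mixture, pruning likelihood, fits, BEB."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from amphisel.codon_model import (
    CodonFrequencies,
    CodonModelParams,
    PruningEngine,
    SiteClassMixture,
    build_rate_matrix,
    estimate_f3x4,
    fit_gene,
    log_likelihood,
    mean_rate,
    mixture_scale_factor,
    site_class_assignments,
    transition_matrix,
)
from amphisel.codons import CODON_INDEX, SENSE_CODONS
from amphisel.io_core import CodonAlignment, parse_labeled_tree
from amphisel.synthetic_data import (
    SimulationSpec,
    default_mixture,
    simulate_codon_alignment,
)
from oracles import enumeration_loglik


UNIFORM_PI = np.full(61, 1.0 / 61)


class TestF3x4:
    def test_uniform_nucleotides_give_uniform_codons(self):
        # each nucleotide once per position across four rows
        rows = [("a", "TTT"), ("b", "CCC"), ("c", "AAA"), ("d", "GGG")]
        freqs = estimate_f3x4(CodonAlignment.from_records(rows), floor=0.0)
        assert freqs.pi == pytest.approx(np.full(61, 1 / 61))

    def test_degenerate_single_codon(self):
        aln = CodonAlignment.from_records([("a", "ATG"), ("b", "ATG")])
        freqs = estimate_f3x4(aln, floor=0.0)
        assert freqs.pi[CODON_INDEX["ATG"]] == pytest.approx(1.0)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(5)
        rows = [
            (f"t{i}", "".join(rng.choice(list("ACGT"), size=60)))
            for i in range(6)
        ]
        aln = CodonAlignment.from_records(rows)
        freqs = estimate_f3x4(aln, floor=0.0)
        # independent position-frequency product
        counts = np.zeros((3, 4))
        for _, seq in rows:
            for k in range(0, 60, 3):
                for pos in range(3):
                    counts[pos, "TCAG".index(seq[k + pos])] += 1
        fr = counts / counts.sum(axis=1, keepdims=True)
        pi = np.array(
            [fr[0, "TCAG".index(c[0])] * fr[1, "TCAG".index(c[1])]
             * fr[2, "TCAG".index(c[2])] for c in SENSE_CODONS]
        )
        pi /= pi.sum()
        assert np.abs(freqs.pi - pi).max() < 1e-12

    def test_gap_only_alignment_raises(self):
        aln = CodonAlignment.from_records([("a", "---"), ("b", "---")])
        with pytest.raises(ValueError):
            estimate_f3x4(aln)


class TestRateMatrix:
    def test_definition_forced_entries(self):
        pi = CodonFrequencies.uniform()
        q = build_rate_matrix(2.0, 0.5, pi)
        i = {c: CODON_INDEX[c] for c in ("AAA", "AAG", "AAC", "AGG")}
        # Lys->Lys transition; Lys->Asn transversion; two-position change
        assert q[i["AAA"], i["AAG"]] == pytest.approx(2.0 * pi.pi[i["AAG"]])
        assert q[i["AAA"], i["AAC"]] == pytest.approx(0.5 * pi.pi[i["AAC"]])
        assert q[i["AAA"], i["AGG"]] == 0.0

    def test_rows_sum_to_zero(self):
        q = build_rate_matrix(3.1, 1.7, CodonFrequencies.uniform())
        assert np.abs(q.sum(axis=1)).max() < 1e-12

    @pytest.mark.parametrize("t", [0.01, 0.1, 0.5, 2.0])
    def test_transition_matrix_vs_expm_oracle(self, t):
        pi = CodonFrequencies.uniform()
        q = build_rate_matrix(2.0, 0.3, pi)
        p = transition_matrix(2.0, 0.3, pi.pi, t)
        p_oracle = scipy.linalg.expm(q * t)
        assert np.abs(p - p_oracle).max() < 1e-6
        assert np.abs(p.sum(axis=1) - 1.0).max() < 1e-8

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_rate_matrix(-1.0, 0.5, CodonFrequencies.uniform())
        with pytest.raises(ValueError):
            build_rate_matrix(2.0, 0.5, np.full(61, -1.0 / 61))


class TestSiteClassMixture:
    def test_forced_proportions(self):
        m = SiteClassMixture(p0=0.5, p1=0.3, omega0=0.1, omega2=2.0)
        assert m.p2a == pytest.approx(0.125)
        assert m.p2b == pytest.approx(0.075)

    def test_degenerate_two_class(self):
        m = SiteClassMixture(p0=0.6, p1=0.4, omega0=0.1, omega2=2.0)
        assert m.p2a == pytest.approx(0.0)
        assert m.p2b == pytest.approx(0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p0=st.floats(0.01, 0.98),
        frac=st.floats(0.01, 0.99),
        w0=st.floats(0.01, 0.99),
        w2=st.floats(1.0, 50.0),
    )
    def test_proportions_sum_to_one(self, p0, frac, w0, w2):
        p1 = (1 - p0) * frac
        m = SiteClassMixture(p0=p0, p1=p1, omega0=w0, omega2=w2)
        assert m.proportions().sum() == pytest.approx(1.0)

    def test_class_assignments_shape(self):
        m = SiteClassMixture(p0=0.5, p1=0.3, omega0=0.1, omega2=3.0)
        classes = site_class_assignments(m)
        assert [c[1:] for c in classes] == [
            (0.1, 0.1), (1.0, 1.0), (0.1, 3.0), (1.0, 3.0)
        ]

    def test_zero_class_weights_rejected(self):
        m = SiteClassMixture(p0=0.0, p1=0.0, omega0=0.1, omega2=2.0)
        with pytest.raises(ValueError, match="p0 \\+ p1"):
            _ = m.p2a


class TestLikelihood:
    def test_zero_distance_identical_sequences(self):
        tree = parse_labeled_tree("(A:0,B:0);")
        aln = CodonAlignment.from_records([("A", "ATGAAA"), ("B", "ATGAAA")])
        pi = estimate_f3x4(aln)
        params = CodonModelParams(
            kappa=2.0,
            mixture=SiteClassMixture(0.5, 0.3, 0.1, 1.0),
            pi=pi,
        )
        expected = sum(
            np.log(pi.pi[CODON_INDEX[c]]) for c in ("ATG", "AAA")
        )
        assert log_likelihood(aln, tree, params) == pytest.approx(expected)

    def test_taxon_order_invariance(self, selection_tree):
        spec = SimulationSpec(
            tree=selection_tree, mixture=default_mixture(2.0),
            n_codons=40, seed=8,
        )
        aln, _ = simulate_codon_alignment(spec)
        params = CodonModelParams(
            kappa=2.0, mixture=default_mixture(2.0),
            pi=CodonFrequencies.uniform(),
        )
        ll1 = log_likelihood(aln, selection_tree, params)
        order = np.argsort([hash(t) for t in aln.taxa])
        shuffled = CodonAlignment(
            taxa=[aln.taxa[i] for i in order], codons=aln.codons[order]
        )
        ll2 = log_likelihood(shuffled, selection_tree, params)
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_rerooting_invariance(self):
        """Reversible model: lnL identical under a different rooting that
        preserves the foreground branch."""
        t1 = parse_labeled_tree("((A:0.2,B:0.3):0.1,(C#1:0.25,D:0.15):0.1);")
        # same unrooted tree rooted at the C+D ancestral node instead; the
        # foreground (leaf C) branch keeps its length
        t2 = parse_labeled_tree("(C#1:0.25,D:0.15,(A:0.2,B:0.3):0.2);")
        spec = SimulationSpec(
            tree=t1, mixture=default_mixture(3.0), n_codons=60, seed=4
        )
        aln, _ = simulate_codon_alignment(spec)
        params = CodonModelParams(
            kappa=2.0, mixture=default_mixture(3.0),
            pi=CodonFrequencies.uniform(),
        )
        ll1 = log_likelihood(aln, t1, params)
        ll2 = log_likelihood(aln, t2, params)
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_gap_codons_marginalized(self):
        tree = parse_labeled_tree("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        aln = CodonAlignment.from_records(
            [("A", "ATG"), ("B", "---"), ("C", "ATG"), ("D", "NNN")]
        )
        params = CodonModelParams(
            kappa=2.0, mixture=SiteClassMixture(0.5, 0.3, 0.1, 1.0),
            pi=CodonFrequencies.uniform(),
        )
        ll = log_likelihood(aln, tree, params)
        assert np.isfinite(ll)
        # dropping the all-missing taxa entirely gives the same likelihood
        sub = CodonAlignment.from_records([("A", "ATG"), ("C", "ATG")])
        ll_sub = log_likelihood(sub, tree, params)
        assert ll == pytest.approx(ll_sub, abs=1e-9)

    def test_pruning_matches_enumeration_oracle(self):
        rng = np.random.default_rng(99)
        bl = rng.uniform(0.05, 0.5, size=6)
        nwk = (
            f"((A:{bl[0]:.3f},B:{bl[1]:.3f})#1:{bl[2]:.3f},"
            f"(C:{bl[3]:.3f},D:{bl[4]:.3f}):{bl[5]:.3f});"
        )
        tree = parse_labeled_tree(nwk)
        mix = SiteClassMixture(p0=0.45, p1=0.25, omega0=0.12, omega2=3.3)
        spec = SimulationSpec(tree=tree, mixture=mix, n_codons=30, seed=17)
        aln, _ = simulate_codon_alignment(spec)
        eng = PruningEngine(aln, tree)
        ll = float(eng.mixture_loglik(UNIFORM_PI, 2.0, mix).sum())
        oracle = enumeration_loglik(aln, tree, 2.0, mix, UNIFORM_PI)
        assert abs(ll - oracle) < 1e-8


class TestFits:
    def test_alternative_never_below_null(self, null_battery):
        for rec in null_battery:
            assert rec["alt"].lnL >= rec["null"].lnL - 1e-9

    def test_null_fit_fixes_omega2(self, null_battery):
        for rec in null_battery[:10]:
            assert rec["null"].params.mixture.omega2 == 1.0

    def test_parameter_recovery_median(self, power_battery):
        """Genes simulated at omega2=4 recover the foreground ratio."""
        omega2 = [r.omega2_hat for r in power_battery["results"]]
        assert 3.0 <= float(np.median(omega2)) <= 5.0

    def test_fit_is_deterministic_given_seed(self, selection_tree):
        spec = SimulationSpec(
            tree=selection_tree, mixture=default_mixture(1.0),
            n_codons=100, seed=55,
        )
        aln, _ = simulate_codon_alignment(spec)
        f1 = fit_gene(aln, selection_tree, seed=5)
        f2 = fit_gene(aln, selection_tree, seed=5)
        assert f1[0].lnL == f2[0].lnL and f1[1].lnL == f2[1].lnL
        assert f1[1].omega2 == f2[1].omega2


class TestBEB:
    def test_posteriors_sum_to_one(self, beb_battery):
        # pooled arrays are the 2a+2b margin; the per-class normalization is
        # checked through the bound 0 <= posterior <= 1
        for key in ("planted", "null"):
            post = beb_battery[key]
            assert ((post >= -1e-12) & (post <= 1 + 1e-12)).all()

    def test_planted_sites_recovered(self, beb_battery):
        recovery = (beb_battery["planted"] > 0.95).mean()
        assert recovery > 0.8

    def test_null_sites_rarely_flagged(self, beb_battery):
        assert (beb_battery["null"] > 0.95).mean() < 0.02

    def test_requires_alternative_converged_fit(self, selection_tree):
        from amphisel.codon_model import beb_site_posteriors, fit_branch_site

        spec = SimulationSpec(
            tree=selection_tree, mixture=default_mixture(1.0),
            n_codons=60, seed=2,
        )
        aln, _ = simulate_codon_alignment(spec)
        null = fit_branch_site(aln, selection_tree, mode="null", seed=0)
        with pytest.raises(ValueError):
            beb_site_posteriors(aln, selection_tree, null)


def test_mixture_scale_factor_normalizes_rate():
    """With the mixture scaling applied, one unit of branch length is one
    expected substitution per codon averaged over background classes."""
    pi = UNIFORM_PI
    m = SiteClassMixture(p0=0.5, p1=0.3, omega0=0.1, omega2=4.0)
    scale = mixture_scale_factor(2.0, m, pi)
    props = m.proportions()
    r0 = mean_rate(build_rate_matrix(2.0, 0.1, pi), pi)
    r1 = mean_rate(build_rate_matrix(2.0, 1.0, pi), pi)
    avg = (props[0] + props[2]) * r0 / scale + (props[1] + props[3]) * r1 / scale
    assert avg == pytest.approx(1.0)
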