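"""Binomial mixture EM, selection verdicts and per-cell mutation calling."""

import numpy as np
import pytest
from scipy.stats import binom, chi2

from xcilineage.clonal_selection import (SelectionThresholds, Verdict,
                                         call_cells, fit_binomial_mixture,
                                         logit, lrt_pvalue, select_by_xci,
                                         summarize_selection)


def grid_loglik_oracle(k, n, n_theta=50, n_pi=20):
    """Best mixture log-likelihood over a (theta1, theta2, pi1) grid.

    Independent of the EM implementation: direct scipy pmf evaluation.
    """
    k = np.asarray(k, float)
    n = np.asarray(n, float)
    thetas = np.linspace(1e-4, 0.999, n_theta)
    pis = np.linspace(0.01, 0.99, n_pi)
    lp = np.array([binom.logpmf(k, n, t) for t in thetas])  # (T, S)
    best = -np.inf
    for pi1 in pis:
        ll = np.logaddexp(np.log(pi1) + lp[:, None, :],
                          np.log(1 - pi1) + lp[None, :, :]).sum(axis=-1)
        best = max(best, float(ll.max()))
    return best


class TestLogit:
    def test_reference_values(self):
        assert logit(0.5) == 0.0
        assert logit(0.04) == pytest.approx(np.log(0.04 / 0.96))
        assert logit(0.04) == pytest.approx(-3.178, abs=1e-3)
        assert abs(logit(0.2) - logit(0.01)) == pytest.approx(3.209, abs=1e-3)
        assert abs(logit(0.045) - logit(0.035)) == pytest.approx(0.262, abs=1e-3)

    def test_clamped_outside_open_interval(self):
        assert logit(0.0) == logit(1e-6)
        assert logit(1.0) == pytest.approx(-logit(0.0))

    def test_antisymmetry(self):
        for p in (0.01, 0.2, 0.5, 0.9):
            assert logit(p) == pytest.approx(-logit(1 - p))


class TestFitBinomialMixture:
    def test_clear_two_component_instance_matches_grid_oracle(self):
        k = np.concatenate([np.full(10, 50.0), np.zeros(90)])
        n = np.full(100, 100.0)
        fit = fit_binomial_mixture(k, n)
        assert fit.converged
        assert fit.theta1 == pytest.approx(0.5, abs=0.01)
        assert fit.theta2 < 1e-4
        assert fit.pi1 == pytest.approx(0.1, abs=0.02)
        assert fit.two_components_supported
        assert fit.loglik >= grid_loglik_oracle(k, n) - 1e-6

    def test_all_zero_counts_degenerate(self):
        k = np.zeros(50)
        n = np.full(50, 100.0)
        fit = fit_binomial_mixture(k, n)
        assert fit.theta1 <= 1e-5 and fit.theta2 <= 1e-5
        assert not fit.theta1 > 0.04  # downstream heteroplasmy test fails
        assert not fit.two_components_supported

    def test_insufficient_cells_raises(self):
        with pytest.raises(ValueError, match="insufficient cells"):
            fit_binomial_mixture(np.array([1.0]), np.array([10.0]), min_cells=2)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError, match="k > n"):
            fit_binomial_mixture(np.array([5.0, 1.0]), np.array([2.0, 10.0]))

    def test_component_order_theta1_ge_theta2(self, rng):
        for _ in range(10):
            n = rng.poisson(50, 100).astype(float)
            k = rng.binomial(n.astype(int), rng.uniform(0.01, 0.3)).astype(float)
            fit = fit_binomial_mixture(k, n)
            assert fit.theta1 >= fit.theta2

    def test_loglik_beats_grid_oracle_on_random_small_instances(self, rng):
        for _ in range(5):
            S = int(rng.integers(50, 200))
            n = rng.integers(5, 50, S).astype(float)
            mutated = rng.random(S) < 0.1
            theta = np.where(mutated, 0.3, 0.01)
            k = rng.binomial(n.astype(int), theta).astype(float)
            fit = fit_binomial_mixture(k, n)
            assert fit.loglik >= grid_loglik_oracle(k, n) - 1e-6

    def test_single_component_data_is_not_split(self, rng):
        # homogeneous error counts: the parsimony check must reject the
        # two-component fit and expose the pooled rate instead
        n = np.full(500, 100.0)
        k = rng.binomial(100, 0.01, 500).astype(float)
        fit = fit_binomial_mixture(k, n)
        assert not fit.two_components_supported
        assert fit.effective_theta1 == pytest.approx(k.sum() / n.sum())

    def test_parameter_recovery_on_planted_mixture(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = rng.poisson(100, 2000).astype(float)
            mutated = rng.random(2000) < 0.05
            k = rng.binomial(n.astype(int),
                             np.where(mutated, 0.10, 0.005)).astype(float)
            fit = fit_binomial_mixture(k[n > 0], n[n > 0])
            hits += abs(fit.theta1 - 0.10) < 0.02
        assert hits >= 4


class TestLrtPvalue:
    def test_zero_counts_favor_null(self):
        # ll_H0 = 100 ln 0.99 > ll_H1 = 100 ln 0.96 -> statistic clamped at 0
        assert lrt_pvalue(0, 100, 0.01, 0.04) == pytest.approx(1.0)

    def test_reference_statistic_value(self):
        stat = -2 * (10 * np.log(0.01 / 0.10) + 90 * np.log(0.99 / 0.90))
        assert stat == pytest.approx(28.9, abs=0.05)
        assert lrt_pvalue(10, 100, 0.01, 0.10) == pytest.approx(
            chi2.sf(stat, 1), rel=1e-12)
        assert lrt_pvalue(10, 100, 0.01, 0.10) == pytest.approx(7.6e-8, rel=0.02)

    def test_null_typical_counts_give_p_near_one(self):
        assert lrt_pvalue(1, 100, 0.01, 0.1) == pytest.approx(1.0, abs=0.05)


class TestCallCells:
    def setup_method(self):
        from xcilineage.clonal_selection import MixtureFit

        self.fit = MixtureFit(pi1=0.1, theta1=0.2, theta2=0.01, loglik=0.0,
                              converged=True, n_cells=100,
                              responsibilities=np.zeros(100),
                              theta_single=0.03, loglik_single=-1.0,
                              two_components_supported=True)

    def test_posterior_reference_value(self):
        post = (0.1 * binom.pmf(5, 20, 0.2)
                / (0.1 * binom.pmf(5, 20, 0.2) + 0.9 * binom.pmf(5, 20, 0.01)))
        assert post == pytest.approx(0.99993, abs=5e-5)
        carrier, posterior, p = call_cells(self.fit, np.array([5.0]),
                                           np.array([20.0]))
        assert posterior[0] == pytest.approx(post, rel=1e-9)
        assert p[0] < 0.05 and carrier[0]

    def test_zero_counts_never_called(self):
        carrier, posterior, _ = call_cells(self.fit, np.zeros(3),
                                           np.array([10.0, 100.0, 1000.0]))
        assert not carrier.any()
        assert (posterior < 0.95).all()

    def test_zero_coverage_cell_sentinel(self):
        carrier, posterior, p = call_cells(self.fit, np.zeros(1), np.zeros(1))
        assert not carrier[0] and np.isnan(posterior[0]) and np.isnan(p[0])

    def test_posterior_boundary_is_strict(self):
        thr = SelectionThresholds()
        # engineer a posterior of exactly 0.95 via the threshold comparison
        carrier = (np.array([0.95]) > thr.posterior_min) & (np.array([0.01]) < thr.alpha)
        assert not carrier[0]


def _planted_variant(rng, h_allele1=0.2, h_allele2=None, error=0.01,
                     n_cells=400, n_cov=100, frac=0.1):
    """k, n, labels with carriers planted in one or both XCI groups."""
    labels = np.where(rng.random(n_cells) < 0.5, "allele1", "allele2").astype(object)
    theta = np.full(n_cells, error)
    for allele, h in (("allele1", h_allele1), ("allele2", h_allele2)):
        if h is None:
            continue
        members = np.flatnonzero(labels == allele)
        chosen = rng.choice(members, size=max(1, int(frac * n_cells / 2)),
                            replace=False)
        theta[chosen] = h
    n = np.full(n_cells, float(n_cov))
    k = rng.binomial(n_cov, theta).astype(float)
    return k, n, labels, theta


class TestSelectByXci:
    def test_clonal_variant_passes_with_correct_allele(self, rng):
        k, n, labels, theta = _planted_variant(rng, h_allele1=0.2)
        res = select_by_xci(k, n, labels)
        assert res.verdict is Verdict.PASS
        assert res.passing_allele == "allele1"
        assert res.logit_diff > 1.22
        # carriers confined to the passing allele
        assert set(labels[res.carrier]) == {"allele1"}
        # every true carrier with clear signal is called
        true_carriers = (theta == 0.2) & (k >= 10)
        assert res.carrier[true_carriers].mean() > 0.9

    def test_pre_xci_variant_fails_both(self, rng):
        k, n, labels, _ = _planted_variant(rng, h_allele1=0.2, h_allele2=0.2)
        res = select_by_xci(k, n, labels)
        assert res.verdict is Verdict.FAIL_BOTH

    def test_error_only_variant_fails_neither(self, rng):
        k, n, labels, _ = _planted_variant(rng, h_allele1=None)
        res = select_by_xci(k, n, labels)
        assert res.verdict is Verdict.FAIL_NEITHER

    def test_logit_gap_rule_close_heteroplasmies(self):
        # deterministic counts engineered so the groups fit ~0.045 vs ~0.035:
        # one above / one below 0.04 but |dlogit| ~ 0.26 < 1.22
        n_half = 200
        k1 = np.full(n_half, 4.5 * 10)
        k2 = np.full(n_half, 3.5 * 10)
        n = np.full(2 * n_half, 1000.0)
        k = np.concatenate([k1, k2])
        labels = np.array(["allele1"] * n_half + ["allele2"] * n_half, dtype=object)
        res = select_by_xci(k, n, labels)
        assert res.verdict is Verdict.FAIL_LOGIT
        assert res.logit_diff == pytest.approx(abs(logit(0.045) - logit(0.035)),
                                               abs=0.02)

    def test_small_group_indeterminate(self, rng):
        k, n, labels, _ = _planted_variant(rng, n_cells=30)
        labels[:] = "allele1"
        labels[:3] = "allele2"
        res = select_by_xci(k, n, labels)
        assert res.verdict is Verdict.INDETERMINATE

    def test_label_swap_flips_passing_allele_not_verdict(self, rng):
        k, n, labels, _ = _planted_variant(rng, h_allele1=0.2)
        res1 = select_by_xci(k, n, labels)
        swap = {"allele1": "allele2", "allele2": "allele1"}
        res2 = select_by_xci(k, n,
                             np.array([swap[l] for l in labels], dtype=object))
        assert res1.verdict == res2.verdict == Verdict.PASS
        assert res2.passing_allele == swap[res1.passing_allele]
        assert res1.logit_diff == pytest.approx(res2.logit_diff)

    def test_unassigned_cells_excluded(self, rng):
        k, n, labels, _ = _planted_variant(rng, h_allele1=0.2)
        labels[::7] = "unassigned"
        res = select_by_xci(k, n, labels)
        assert res.verdict is Verdict.PASS
        assert not res.carrier[labels == "unassigned"].any()


def test_summarize_selection_taxonomy(rng):
    results = {}
    for i, (h1, h2) in enumerate([(0.2, None), (0.2, 0.2), (None, None)]):
        k, n, labels, _ = _planted_variant(rng, h_allele1=h1, h_allele2=h2)
        results[f"v{i}"] = select_by_xci(k, n, labels)
    counts = summarize_selection(results)
    assert counts["input"] == 3
    assert counts["pass"] == 1
    assert counts["fail_both"] == 1
    assert counts["fail_neither"] == 1
    # variants clearing the clonal-heteroplasmy bar in >=1 group: PASS + FAIL_BOTH
    assert counts["heteroplasmy_pass"] == 2
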