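import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromregime.enrichment_model import (
    FitError,
    estimate_pseudo_counts,
    fit_binomial_mixture,
    mixture_loglik,
    normalize_enrichment,
    posterior_labels,
    raw_enrichment,
)
from oracles import grid_search_loglik


class TestFit:
    def test_parameter_recovery_on_reference_run(self, mixture_run):
        fit = mixture_run["fit"]
        cfg = mixture_run["cfg"]
        assert abs(fit.theta_bg - cfg.theta_bg) < 0.02
        assert abs(fit.theta_sig - cfg.theta_sig) < 0.02
        assert abs(fit.pi_bg - cfg.pi_bg) < 0.02

    def test_loglik_trace_is_monotone(self, mixture_run):
        trace = mixture_run["fit"].loglik_trace
        assert np.all(np.diff(trace) >= -1e-9)

    def test_recovery_bias_shrinks_with_n(self):
        from chromregime.synthetic_data import SimConfig, simulate_counts

        errors = []
        for n in (1_000, 10_000):
            counts, _ = simulate_counts(SimConfig(n_regions=n, seed=42))
            fit = fit_binomial_mixture(counts, seed=0)
            errors.append(abs(fit.theta_sig - 0.8) + abs(fit.theta_bg - 0.5))
        assert errors[1] <= errors[0] + 0.005

    def test_symmetric_data_collapses_components(self):
        s = np.full(200, 5)
        r = np.full(200, 5)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            fit = fit_binomial_mixture((s, r), seed=0)
        assert abs(fit.theta_bg - 0.5) < 0.01
        assert abs(fit.theta_sig - 0.5) < 0.01

    def test_single_region_completes_with_warning(self):
        with pytest.warns(RuntimeWarning):
            fit = fit_binomial_mixture((np.array([3]), np.array([1])), seed=0)
        assert 0.0 <= fit.posterior[0] <= 1.0
        assert fit.degenerate

    def test_all_zero_totals_rejected(self):
        with pytest.raises(FitError, match="no informative regions"):
            fit_binomial_mixture((np.zeros(5, int), np.zeros(5, int)))

    def test_em_reaches_grid_search_likelihood(self):
        rng = np.random.default_rng(5)
        for trial in range(3):
            n = rng.integers(1, 7, size=rng.integers(4, 13))
            s = rng.binomial(n, rng.choice([0.3, 0.8], size=len(n)))
            r = n - s
            fit = fit_binomial_mixture((s, r), restarts=8, seed=trial)
            em_ll = mixture_loglik(s, r, fit.theta_bg, fit.theta_sig, fit.pi_bg)
            grid_ll = grid_search_loglik(s, r, step=0.01)
            assert em_ll >= grid_ll - 1e-6


class TestPseudoCounts:
    def test_background_proportional_rule(self, mixture_run):
        fit = mixture_run["fit"]
        alpha_s, alpha_r = fit.alpha_s, fit.alpha_r
        assert alpha_s == pytest.approx(fit.theta_bg)
        assert alpha_r == pytest.approx(1 - fit.theta_bg)

    def test_symmetric_background(self):
        fit = _fake_fit(theta_bg=0.5)
        assert estimate_pseudo_counts(fit, c=1.0) == (0.5, 0.5)

    def test_skewed_background_ratio(self):
        fit = _fake_fit(theta_bg=0.2)
        alpha_s, alpha_r = estimate_pseudo_counts(fit, c=1.0)
        assert (alpha_s, alpha_r) == (pytest.approx(0.2), pytest.approx(0.8))
        assert alpha_r / alpha_s == pytest.approx(4.0)

    def test_region_at_background_ratio_scores_zero(self):
        # theta_bg = 0.2 means the background ChIP:control ratio is 1:4
        alpha_s, alpha_r = 0.2, 0.8
        e = raw_enrichment((np.array([250]), np.array([1000])), alpha_s, alpha_r)
        assert abs(e[0]) < 1e-3

    def test_scale_property_preserves_zero_point(self):
        # doubling both pseudo counts changes shrinkage, not the zero ratio
        e1 = raw_enrichment((np.array([50]), np.array([200])), 0.2, 0.8)
        e2 = raw_enrichment((np.array([50]), np.array([200])), 0.4, 1.6)
        assert abs(e1[0]) < 0.02 and abs(e2[0]) < 0.02

    def test_degenerate_theta_rejected(self):
        with pytest.raises(FitError):
            estimate_pseudo_counts(_fake_fit(theta_bg=1.0))


def _fake_fit(theta_bg=0.5, theta_sig=0.8, posterior=None):
    from chromregime.enrichment_model import MixtureFit

    return MixtureFit(
        theta_bg=theta_bg,
        theta_sig=theta_sig,
        pi_bg=0.9,
        posterior=np.asarray(posterior if posterior is not None else [0.5]),
        loglik_trace=np.array([0.0]),
        converged=True,
        n_iter=1,
    )


class TestRawEnrichment:
    def test_empty_region_scores_exactly_zero(self):
        e = raw_enrichment((np.array([0]), np.array([0])), 0.5, 0.5)
        assert e[0] == 0.0

    def test_worked_example(self):
        e = raw_enrichment((np.array([10]), np.array([5])), 1.0, 2.0)
        assert e[0] == pytest.approx(math.log(22 / 7), abs=1e-10)

    def test_symmetry_under_count_swap(self):
        e_fwd = raw_enrichment((np.array([10]), np.array([5])), 1.0, 1.0)
        e_rev = raw_enrichment((np.array([5]), np.array([10])), 1.0, 1.0)
        assert e_fwd[0] == pytest.approx(-e_rev[0])

    def test_nonpositive_pseudo_counts_rejected(self):
        with pytest.raises(ValueError):
            raw_enrichment((np.array([1]), np.array([1])), 0.0, 1.0)

    @given(
        s=st.integers(0, 500), r=st.integers(0, 500),
        alpha=st.floats(0.05, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_counts(self, s, r, alpha):
        base = raw_enrichment((np.array([s]), np.array([r])), alpha, alpha)[0]
        more_s = raw_enrichment((np.array([s + 1]), np.array([r])), alpha, alpha)[0]
        more_r = raw_enrichment((np.array([s]), np.array([r + 1])), alpha, alpha)[0]
        assert more_s > base
        assert more_r < base


class TestNormalization:
    def test_weighted_mean_rule(self):
        fit = _fake_fit(posterior=[1.0, 1.0])
        frame = normalize_enrichment(np.array([1.5, 2.5]), fit)
        assert fit.ln_f == pytest.approx(2.0)
        assert list(frame["e"]) == [pytest.approx(0.75), pytest.approx(1.25)]

    def test_zero_posterior_regions_excluded(self):
        fit = _fake_fit(posterior=[1.0, 0.0])
        normalize_enrichment(np.array([2.0, 7.0]), fit)
        assert fit.ln_f == pytest.approx(2.0)

    def test_zero_e_star_maps_to_zero(self):
        fit = _fake_fit(posterior=[1.0, 0.5])
        frame = normalize_enrichment(np.array([0.0, 3.0]), fit)
        assert frame["e"].iloc[0] == 0.0

    def test_non_enriched_signal_component_rejected(self):
        fit = _fake_fit(posterior=[1.0, 1.0])
        with pytest.raises(FitError, match="swapped"):
            normalize_enrichment(np.array([-1.0, -2.0]), fit)

    def test_signal_mean_is_one_after_normalization(self, mixture_run):
        scores = mixture_run["scores"]
        post = scores["posterior"].to_numpy()
        mean_sig = np.dot(post, scores["e"]) / post.sum()
        assert mean_sig == pytest.approx(1.0, abs=1e-12)


class TestPosteriorLabels:
    def test_boundary_is_inclusive(self):
        fit = _fake_fit(posterior=[0.5, 0.49])
        assert list(posterior_labels(fit, 0.5)) == ["sig", "bg"]

    def test_threshold_one_with_sub_unit_posteriors(self):
        fit = _fake_fit(posterior=[0.99, 0.2])
        assert list(posterior_labels(fit, 1.0)) == ["bg", "bg"]

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            posterior_labels(_fake_fit(), threshold=1.5)

    def test_label_accuracy_on_reference_run(self, mixture_run):
        labels = posterior_labels(mixture_run["fit"])
        assert (labels == mixture_run["labels"]).mean() >= 0.95
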