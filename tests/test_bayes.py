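"""Variance components and the conjugate normal-normal personal interval."""

import math

import numpy as np
import pytest

from intraref import (
    PriorParams,
    SimulationParams,
    VarianceComponents,
    bayes_interval,
    estimate_components,
    generate_panel,
    posterior,
)

from conftest import make_panel

# Mixed-model components at serum-transferrin scale used throughout:
# between-subject variance 770.96 (SD 27.77), within-subject 165.95 (SD 12.88).
TRF_BETWEEN, TRF_WITHIN = 770.96, 165.95


def brute_force_components(X: np.ndarray):
    """Independent oracle: explicit mean-squares loops on an S x T matrix."""
    S, T = X.shape
    grand = sum(X[i][j] for i in range(S) for j in range(T)) / (S * T)
    visit_means = [sum(X[i][j] for i in range(S)) / S for j in range(T)]
    subj_means = [sum(X[i][j] for j in range(T)) / T for i in range(S)]
    ss_resid = sum(
        (X[i][j] - subj_means[i] - visit_means[j] + grand) ** 2
        for i in range(S)
        for j in range(T)
    )
    within = ss_resid / ((S - 1) * (T - 1))
    ms_between = T * sum((m - grand) ** 2 for m in subj_means) / (S - 1)
    between = max(0.0, (ms_between - within) / T)
    return between, within, [v - grand for v in visit_means]


class TestEstimateComponents:
    def test_constant_panel_all_zero(self):
        panel = make_panel({f"S{i}": [100] * 3 for i in range(3)})
        with pytest.warns(UserWarning, match="zero total variance"):
            comp = estimate_components(panel)
        assert comp.between_var == comp.within_var == 0.0
        assert all(v == 0.0 for v in comp.visit_effects)

    def test_two_by_two_hand_case(self):
        # subjects at 0 and 2, no within-subject scatter
        comp = estimate_components(make_panel({"A": [0, 0], "B": [2, 2]}))
        assert comp.visit_effects == (0.0, 0.0)
        assert comp.within_var == 0.0
        assert comp.between_var == pytest.approx(2.0)

    def test_oracle_equivalence_on_random_small_panels(self):
        """Moment estimator equals brute-force mean squares on 200 random
        balanced panels with S, T <= 4."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            S, T = rng.integers(2, 5), rng.integers(2, 5)
            X = rng.normal(50, 10, (S, T)) + rng.normal(0, 5, (S, 1))
            panel = make_panel({f"S{i:02d}": X[i] for i in range(S)})
            comp = estimate_components(panel)
            b, w, ve = brute_force_components(X)
            assert comp.between_var == pytest.approx(b, rel=1e-10, abs=1e-10)
            assert comp.within_var == pytest.approx(w, rel=1e-10)
            assert np.allclose(comp.visit_effects, ve)

    def test_recovers_generative_components_at_large_n(self):
        params = SimulationParams(
            mu0=280,
            sigma0=math.sqrt(TRF_BETWEEN),
            sigma_eps=math.sqrt(TRF_WITHIN),
            n_subjects=500,
            n_visits=5,
            seed=12345,
        )
        comp = estimate_components(generate_panel(params))
        assert comp.between_var == pytest.approx(TRF_BETWEEN, rel=0.10)
        assert comp.within_var == pytest.approx(TRF_WITHIN, rel=0.10)

    def test_visit_effects_recovered_and_removed(self):
        ve = (5.0, -3.0, -2.0)
        params = SimulationParams(
            mu0=100,
            sigma0=10,
            sigma_eps=0.5,
            visit_effects=ve,
            n_subjects=200,
            n_visits=3,
            seed=5,
        )
        comp = estimate_components(generate_panel(params))
        assert np.allclose(comp.visit_effects, ve, atol=0.2)
        assert comp.within_var == pytest.approx(0.25, rel=0.25)

    def test_unbalanced_panel_rejected(self):
        panel = make_panel({"A": [1, 2, 3], "B": [4, 5]})
        with pytest.raises(ValueError, match="balanced"):
            estimate_components(panel)

    def test_agrees_with_reml_mixed_model(self, trf_panel):
        """Independent cross-check: statsmodels MixedLM (REML) on the same
        panel with visit fixed effects gives the same components (balance
        makes the moment and likelihood solutions coincide)."""
        statsmodels = pytest.importorskip("statsmodels.formula.api")
        df = trf_panel.data.assign(visit=trf_panel.data["visit_index"].astype(str))
        md = statsmodels.mixedlm("value ~ C(visit)", df, groups=df["subject_id"])
        fit = md.fit(reml=True)
        comp = estimate_components(trf_panel)
        assert float(fit.cov_re.iloc[0, 0]) == pytest.approx(comp.between_var, rel=1e-4)
        assert float(fit.scale) == pytest.approx(comp.within_var, rel=1e-4)


class TestVarianceComponentsContracts:
    def test_sd_identities_on_reported_components(self):
        # transferrin: between 770.96, within 165.95
        comp = VarianceComponents(TRF_BETWEEN, TRF_WITHIN)
        assert round(comp.total_sd, 2) == 30.61
        assert round(comp.within_sd, 2) == 12.88
        assert round(comp.between_sd, 2) == 27.77
        # retinol-binding protein: between 1.13, within 0.10
        rbp = VarianceComponents(1.13, 0.10)
        assert round(rbp.total_sd, 2) == 1.11
        assert round(rbp.between_sd, 2) == 1.06
        assert round(rbp.within_sd, 2) == 0.32
        # transthyretin between-SD
        assert round(VarianceComponents(47.29, 0.0).between_sd, 2) == 6.88

    def test_negative_components_rejected(self):
        with pytest.raises(ValueError):
            VarianceComponents(-1.0, 1.0)

    def test_unbalanced_visit_effects_rejected(self):
        with pytest.raises(ValueError, match="sum to 0"):
            VarianceComponents(1.0, 1.0, visit_effects=(1.0, 1.0))


class TestPosterior:
    PRIOR = PriorParams(mu0=280.0, sigma0_sq=TRF_BETWEEN)

    def test_no_observations_returns_prior(self):
        post = posterior(self.PRIOR, TRF_WITHIN, [])
        assert (post.mu_n, post.sigma_n_sq) == (280.0, TRF_BETWEEN)
        assert post.shrinkage_weight == 1.0 and post.n == 0

    def test_single_observation_hand_arithmetic(self):
        post = posterior(self.PRIOR, TRF_WITHIN, [240.0])
        assert post.shrinkage_weight == pytest.approx(0.177, abs=5e-4)
        assert post.mu_n == pytest.approx(247.1, abs=0.05)
        assert post.sigma_n_sq == pytest.approx(136.5, abs=0.1)

    def test_shrinkage_limit_large_n(self):
        x = [250.0] * 10_000
        post = posterior(self.PRIOR, TRF_WITHIN, x)
        assert post.mu_n == pytest.approx(250.0, abs=0.01)
        assert post.sigma_n_sq < 0.02

    def test_posterior_never_wider_than_prior_and_convex_mean(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = rng.normal(260, 15, rng.integers(1, 8))
            post = posterior(self.PRIOR, TRF_WITHIN, x)
            assert post.sigma_n_sq <= self.PRIOR.sigma0_sq
            xbar = float(np.mean(x))
            lo, hi = sorted((self.PRIOR.mu0, xbar))
            assert lo - 1e-9 <= post.mu_n <= hi + 1e-9
            if abs(xbar - self.PRIOR.mu0) > 1e-9:
                assert lo < post.mu_n < hi

    def test_zero_within_var_with_data_rejected(self):
        with pytest.raises(ValueError):
            posterior(self.PRIOR, 0.0, [1.0])


class TestBayesInterval:
    PRIOR = PriorParams(mu0=280.0, sigma0_sq=TRF_BETWEEN)

    def test_n0_equals_population_range_from_components(self):
        post = posterior(self.PRIOR, TRF_WITHIN, [])
        i = bayes_interval(post, TRF_WITHIN)
        assert i.lower == pytest.approx(220.0, abs=0.05)
        assert i.upper == pytest.approx(340.0, abs=0.05)

    def test_width_strictly_decreasing_in_n_with_floor(self):
        z, within_sd = 1.96, math.sqrt(TRF_WITHIN)
        widths = []
        for n in range(0, 30):
            post = posterior(self.PRIOR, TRF_WITHIN, [275.0] * n)
            widths.append(bayes_interval(post, TRF_WITHIN).width)
        assert all(a > b for a, b in zip(widths, widths[1:]))
        assert all(w > 2 * z * within_sd for w in widths)
        # n -> infinity limit
        post = posterior(self.PRIOR, TRF_WITHIN, [275.0] * 100_000)
        assert bayes_interval(post, TRF_WITHIN).width == pytest.approx(
            2 * z * within_sd, rel=1e-3
        )

    def test_degenerate_prior_pins_center_at_mu0(self):
        prior = PriorParams(mu0=280.0, sigma0_sq=0.0)
        post = posterior(prior, TRF_WITHIN, [100.0, 400.0])
        i = bayes_interval(post, TRF_WITHIN)
        assert i.center == 280.0
        assert i.width == pytest.approx(2 * 1.96 * math.sqrt(TRF_WITHIN))

    def test_n5_interval_narrower_than_population_range(self):
        """After five visits the personal range beats the routine 190-340
        population range, whatever the five values are (width does not
        depend on the data)."""
        post = posterior(self.PRIOR, TRF_WITHIN, [280.0] * 5)
        i = bayes_interval(post, TRF_WITHIN)
        assert i.width < 340 - 190
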