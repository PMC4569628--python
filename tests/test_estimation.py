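"""Parameter recovery, estimator bias, beta-route consistency, equivariance."""

from dataclasses import replace

import numpy as np
import pytest

from phycofit import (
    InsufficientDataError,
    LogisticGrowthModel,
    LogisticParams,
    LuedekingPiretModel,
    LuedekingPiretParams,
    NonIdentifiableError,
    TimeSeriesDataset,
    beta_stationary,
    fit_condition,
    fit_logistic,
    fit_luedeking_piret,
    generate_dataset,
    preset,
)

from conftest import CONDITIONS, P0, X0, XS


def noiseless_dataset(condition: str) -> TimeSeriesDataset:
    return generate_dataset(preset(condition))


class TestLogisticRecovery:
    @pytest.mark.parametrize("condition", list(CONDITIONS))
    def test_noiseless_roundtrip(self, condition):
        """All three growth parameters come back from noiseless data."""
        k_true = CONDITIONS[condition][0]
        growth, r2, pct = fit_logistic(noiseless_dataset(condition))
        assert growth.k == pytest.approx(k_true, rel=1e-4)
        assert growth.x0 == pytest.approx(X0, rel=1e-4)
        assert growth.xs == pytest.approx(XS, rel=1e-4)
        assert r2 >= 0.999999
        assert pct <= 1e-6

    def test_unbiased_under_measurement_noise(self):
        """Replicated fits of noisy data: mean k-hat within 2 MC standard
        errors of the generating value (sigma = 0.02 g/L)."""
        cfg = preset("C. salina N+", noise_sd_biomass=0.02)
        k_hats = []
        for seed in range(200):
            data = generate_dataset(replace(cfg, seed=seed))
            growth, _, _ = fit_logistic(data)
            k_hats.append(growth.k)
        k_hats = np.asarray(k_hats)
        mc_se = k_hats.std(ddof=1) / np.sqrt(k_hats.size)
        assert abs(k_hats.mean() - 0.4441) <= 2 * mc_se

    def test_constant_biomass_unidentifiable(self):
        with pytest.raises(NonIdentifiableError):
            LogisticGrowthModel().fit(np.arange(6.0), np.full(6, 1.5))

    def test_decreasing_biomass_unidentifiable(self):
        with pytest.raises(NonIdentifiableError):
            LogisticGrowthModel().fit(
                np.arange(6.0), np.array([2.0, 1.8, 1.5, 1.1, 0.7, 0.4])
            )

    def test_too_few_timepoints(self):
        with pytest.raises(InsufficientDataError):
            LogisticGrowthModel().fit([0.0, 1.0, 2.0], [0.1, 0.2, 0.4])

    def test_deterministic_refit(self, default_grid):
        data = noiseless_dataset("N. oculata N+")
        a = LogisticGrowthModel().fit(data.times, data.biomass)
        b = LogisticGrowthModel().fit(data.times, data.biomass)
        assert (a.x0_, a.k_, a.xs_) == (b.x0_, b.k_, b.xs_)


class TestLuedekingPiretRecovery:
    @pytest.mark.parametrize("condition", list(CONDITIONS))
    def test_noiseless_roundtrip(self, condition):
        _, alpha_true, beta_true = CONDITIONS[condition]
        data = noiseless_dataset(condition)
        growth, _, _ = fit_logistic(data)
        prod, r2, pct = fit_luedeking_piret(data, growth)
        assert prod.alpha == pytest.approx(alpha_true, rel=1e-4)
        assert prod.beta == pytest.approx(beta_true, rel=1e-4)
        assert pct <= 1e-6

    def test_alpha_unbiased_under_product_noise(self):
        """With the growth kinetics given, the least-squares alpha estimate
        under product measurement noise is unbiased: its mean over
        replicates stays within 2 MC standard errors of the truth.

        The initial product is offset from zero so the generator's
        nonnegativity truncation never fires; truncation at the p = 0
        boundary is a property of the noise model, not the estimator.
        """
        base = preset("C. salina N+", noise_sd_product=0.005)
        base = replace(
            base, prod=replace(base.prod, p0=0.5), noise_sd_product=0.005
        )
        alpha_hats = []
        for seed in range(200):
            data = generate_dataset(replace(base, seed=seed))
            prod, _, _ = fit_luedeking_piret(data, base.growth)
            alpha_hats.append(prod.alpha)
        alpha_hats = np.asarray(alpha_hats)
        mc_se = alpha_hats.std(ddof=1) / np.sqrt(alpha_hats.size)
        assert abs(alpha_hats.mean() - 0.125) <= 2 * mc_se

    def test_pipeline_alpha_accuracy_under_joint_noise(self):
        """Full pipeline (growth refitted from noisy biomass) propagates
        parameter noise into alpha; the plug-in bias stays below 5%."""
        cfg = preset(
            "C. salina N+", noise_sd_biomass=0.02, noise_sd_product=0.005
        )
        alpha_hats = []
        for seed in range(200):
            data = generate_dataset(replace(cfg, seed=seed))
            growth, _, _ = fit_logistic(data)
            prod, _, _ = fit_luedeking_piret(data, growth)
            alpha_hats.append(prod.alpha)
        assert abs(np.mean(alpha_hats) - 0.125) <= 0.05 * 0.125

    def test_null_product_gives_zero_coefficients(self, csalina_growth):
        t = np.linspace(0.0, 20.0, 30)
        model = LuedekingPiretModel(growth=csalina_growth).fit(t, np.zeros(30))
        assert model.alpha_ == 0.0
        assert model.beta_ == 0.0
        assert np.allclose(model.predict(t), 0.0)

    def test_too_few_timepoints(self, csalina_growth):
        with pytest.raises(InsufficientDataError):
            LuedekingPiretModel(growth=csalina_growth).fit(
                [0.0, 1.0, 2.0], [0.0, 0.1, 0.2]
            )

    def test_requires_growth_params(self):
        with pytest.raises(ValueError):
            LuedekingPiretModel().fit([0.0, 1, 2, 3, 4], [0, 0.1, 0.2, 0.3, 0.4])


class TestBetaStationary:
    def test_definition_inverted_on_flat_window(self):
        # product slope exactly beta*xs over a flat-biomass tail
        t = np.linspace(0.0, 10.0, 11)
        biomass = np.full(11, 2.0)
        product = 0.002 * 2.0 * t
        data = TimeSeriesDataset(times=t, biomass=biomass, product=product)
        assert beta_stationary(data, xs=2.0) == pytest.approx(0.002, rel=1e-12)

    def test_constant_product_gives_zero(self):
        t = np.linspace(0.0, 10.0, 11)
        data = TimeSeriesDataset(
            times=t, biomass=np.full(11, 2.0), product=np.full(11, 0.3)
        )
        assert beta_stationary(data, xs=2.0) == 0.0

    def test_roundtrip_on_long_run(self):
        # long run reaching deep stationary phase: within 5% of truth
        cfg = replace(preset("C. salina N+"), times=np.linspace(0.0, 45.0, 90))
        data = generate_dataset(cfg)
        assert beta_stationary(data, xs=XS) == pytest.approx(0.002, rel=0.05)

    def test_agrees_with_joint_fit(self):
        # long run, strict stationarity window (biomass within 0.5% of its
        # maximum) so the growth-associated term has fully died out
        cfg = replace(preset("N. oculata N-"), times=np.linspace(0.0, 60.0, 120))
        data = generate_dataset(cfg)
        growth, _, _ = fit_logistic(data)
        prod, _, _ = fit_luedeking_piret(data, growth)
        assert beta_stationary(data, growth.xs, rel_tol=0.005) == pytest.approx(
            prod.beta, rel=0.05
        )

    def test_no_stationary_window_detected(self):
        # short run: biomass still climbing at the end
        data = generate_dataset(
            replace(preset("C. salina N+"), times=np.linspace(0.0, 8.0, 20))
        )
        with pytest.raises(NonIdentifiableError, match="joint"):
            beta_stationary(data, xs=XS)


class TestScaleEquivariance:
    def test_concentration_rescaling(self):
        """Multiplying all concentrations by c rescales x0 and xs by c and
        leaves k, alpha and beta unchanged."""
        c = 3.7
        data = noiseless_dataset("C. salina N+")
        scaled = TimeSeriesDataset(
            times=data.times, biomass=c * data.biomass, product=c * data.product
        )
        g1, _, _ = fit_logistic(data)
        g2, _, _ = fit_logistic(scaled)
        assert g2.x0 == pytest.approx(c * g1.x0, rel=1e-5)
        assert g2.xs == pytest.approx(c * g1.xs, rel=1e-5)
        assert g2.k == pytest.approx(g1.k, rel=1e-5)
        p1, _, _ = fit_luedeking_piret(data, g1)
        p2, _, _ = fit_luedeking_piret(scaled, g2)
        assert p2.alpha == pytest.approx(p1.alpha, rel=1e-5)
        assert p2.beta == pytest.approx(p1.beta, rel=1e-5)


class TestFullPipeline:
    def test_fit_condition_returns_class_ii_for_published_regime(self):
        result = fit_condition(noiseless_dataset("C. salina N+"))
        assert str(result.gaden_class) == "II"
        assert result.condition_label == "C. salina N+"
        assert result.r2_growth <= 1.0 and result.r2_product <= 1.0
        assert result.pct_error_growth >= 0.0

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        model = LogisticGrowthModel(max_nfev=500)
        assert model.get_params() == {"max_nfev": 500}
        cloned = clone(model)
        assert cloned.get_params() == {"max_nfev": 500}
        lp = LuedekingPiretModel(growth=LogisticParams(0.05, 0.4, 2.0))
        assert "growth" in lp.get_params()
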