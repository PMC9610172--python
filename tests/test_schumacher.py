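import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from siteform.errors import (
    DegreesOfFreedomError,
    DomainError,
    InsufficientDataError,
    SingularSiteError,
    UnidentifiableError,
)
from siteform.schumacher import (
    ADA,
    GADA,
    GrowthPair,
    SchumacherParams,
    ada_project,
    fit_difference_model,
    fit_plot_height_model,
    fit_statistics,
    gada_project,
    gada_site_variable,
    schumacher_height,
    two_stage_unit_effects,
)
from siteform.simulate import simulate_growth_pairs

TABLE_ADA = SchumacherParams(None, 23.02)
TABLE_GADA = SchumacherParams(534.60, -144.44)


class TestBaseModel:
    def test_flat_curve_when_beta1_zero(self):
        p = SchumacherParams(2.0, 0.0)
        for d in (5.0, 40.0, 400.0):
            assert schumacher_height(d, p) == pytest.approx(1.3 + np.e**2)

    def test_asymptote_at_large_diameter(self):
        p = SchumacherParams(3.5, -25.0)
        assert schumacher_height(1e9, p) == pytest.approx(1.3 + np.exp(3.5), rel=1e-6)

    def test_scalar_oracle(self):
        # 1.3 + exp(3.5 - 25/40) computed independently
        assert schumacher_height(40.0, SchumacherParams(3.5, -25.0)) == pytest.approx(
            1.3 + np.exp(3.5 - 25.0 / 40.0), abs=1e-12
        )
        assert schumacher_height(40.0, SchumacherParams(3.5, -25.0)) == pytest.approx(
            19.03, abs=0.01
        )

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(DomainError):
            schumacher_height(0.0, SchumacherParams(3.5, -25.0))


class TestProjections:
    def test_ada_scalar_oracle(self):
        expected = 1.3 + (15 - 1.3) * np.exp(-23.02 / 40) / np.exp(-23.02 / 25)
        assert ada_project(15.0, 25.0, 40.0, 23.02) == pytest.approx(expected, abs=1e-12)
        assert ada_project(15.0, 25.0, 40.0, 23.02) == pytest.approx(20.65, abs=0.01)

    def test_gada_scalar_oracle(self):
        x0 = (np.log(15 - 1.3) - 534.60 / 25) / (1 - 144.44 / 25)
        expected = 1.3 + np.exp(x0 + (534.60 - 144.44 * x0) / 40)
        assert gada_project(15.0, 25.0, 40.0, TABLE_GADA) == pytest.approx(
            expected, abs=1e-12
        )
        assert gada_project(15.0, 25.0, 40.0, TABLE_GADA) == pytest.approx(
            23.70, abs=0.01
        )

    def test_height_below_breast_height_rejected(self):
        with pytest.raises(DomainError):
            ada_project(1.3, 25.0, 40.0, 23.02)
        with pytest.raises(DomainError):
            gada_project(1.2, 25.0, 40.0, TABLE_GADA)

    def test_singular_site_variable(self):
        with pytest.raises(SingularSiteError):
            gada_site_variable(15.0, 144.44, 534.60, -144.44)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        h1=st.floats(2.0, 45.0),
        d1=st.floats(8.0, 80.0),
        d2=st.floats(8.0, 80.0),
        beta1=st.floats(1.0, 200.0),
    )
    def test_ada_self_referencing_and_path_invariance(self, h1, d1, d2, beta1):
        assert ada_project(h1, d1, d1, beta1) == pytest.approx(h1, abs=1e-9)
        direct = ada_project(h1, d1, d2, beta1)
        assume(direct < 100.0)  # identities checked on tree-height scale
        mid = (d1 + d2) / 2
        via = ada_project(ada_project(h1, d1, mid, beta1), mid, d2, beta1)
        assert via == pytest.approx(direct, abs=1e-9)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        h1=st.floats(2.0, 45.0),
        d1=st.floats(8.0, 80.0),
        d2=st.floats(8.0, 80.0),
    )
    def test_gada_self_referencing_and_path_invariance(self, h1, d1, d2):
        p = TABLE_GADA
        assert gada_project(h1, d1, d1, p) == pytest.approx(h1, abs=1e-9)
        mid = (d1 + d2) / 2
        via = gada_project(gada_project(h1, d1, mid, p), mid, d2, p)
        assert via == pytest.approx(gada_project(h1, d1, d2, p), abs=1e-9)

    def test_gada_site_variable_invariant_along_curve(self):
        h2 = gada_project(15.0, 25.0, 40.0, TABLE_GADA)
        x0_a = gada_site_variable(15.0, 25.0, 534.60, -144.44)
        x0_b = gada_site_variable(h2, 40.0, 534.60, -144.44)
        assert x0_a == pytest.approx(x0_b, abs=1e-10)

    def test_curve_families_do_not_cross(self):
        d2_grid = np.linspace(8.0, 80.0, 50)
        for project in (
            lambda h1, d2: ada_project(h1, 20.0, d2, 23.02),
            lambda h1, d2: gada_project(h1, 20.0, d2, TABLE_GADA),
        ):
            lo = project(10.0, d2_grid)
            hi = project(12.0, d2_grid)
            assert np.all(hi > lo)


class TestFitStatistics:
    def test_perfect_predictions(self):
        st_ = fit_statistics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], p=1)
        assert st_.r2_adj == 1.0 and st_.rmse == 0.0
        assert st_.relative_error() == 0.0

    def test_hand_oracle(self):
        st_ = fit_statistics([10, 12, 14, 16], [11, 11, 15, 15], p=2)
        assert st_.rmse == pytest.approx(np.sqrt(2), abs=1e-12)
        assert st_.r2_adj == pytest.approx(0.70, abs=1e-12)
        assert st_.relative_error() == pytest.approx(np.sqrt(2) / 13 * 100, abs=1e-10)

    def test_null_model_r2_zero(self):
        y = np.array([4.0, 6.0, 8.0, 10.0])
        st_ = fit_statistics(y, np.full(4, y.mean()), p=1)
        assert st_.r2_adj == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n, p = int(rng.integers(5, 60)), int(rng.integers(1, 4))
            y = rng.normal(10, 3, n)
            yhat = y + rng.normal(0, 1, n)
            st_ = fit_statistics(y, yhat, p)
            sse = sum((yi - yh) ** 2 for yi, yh in zip(y, yhat))
            sst = sum((yi - np.mean(y)) ** 2 for yi in y)
            assert st_.r2_adj == pytest.approx(
                1 - (n - 1) * sse / ((n - p) * sst), rel=1e-12
            )
            assert st_.rmse == pytest.approx((sse / (n - p)) ** 0.5, rel=1e-12)
            assert st_.relative_error() == pytest.approx(
                st_.rmse / np.mean(y) * 100, rel=1e-12
            )

    def test_degrees_of_freedom_guard(self):
        with pytest.raises(DegreesOfFreedomError):
            fit_statistics([1.0, 2.0], [1.0, 2.0], p=2)

    def test_relative_error_undefined_at_zero_mean(self):
        st_ = fit_statistics([-1.0, 0.0, 1.0], [0.0, 0.0, 0.0], p=1)
        with pytest.raises(DomainError):
            st_.relative_error()


class TestFitDifferenceModel:
    def test_noiseless_ada_recovery(self):
        rng = np.random.default_rng(0)
        pairs = simulate_growth_pairs(ADA, TABLE_ADA, 50, 0.0, rng)
        fit = fit_difference_model(pairs, ADA)
        assert fit.params.beta1 == pytest.approx(23.02, rel=1e-6)
        assert fit.stats.rmse == pytest.approx(0.0, abs=1e-8)

    def test_noiseless_gada_recovery(self):
        rng = np.random.default_rng(1)
        pairs = simulate_growth_pairs(GADA, TABLE_GADA, 80, 0.0, rng)
        fit = fit_difference_model(pairs, GADA)
        assert fit.params.beta0 == pytest.approx(534.60, rel=1e-4)
        assert fit.params.beta1 == pytest.approx(-144.44, rel=1e-4)

    def test_noisy_ada_recovery_within_5_percent(self):
        rng = np.random.default_rng(2)
        pairs = simulate_growth_pairs(ADA, TABLE_ADA, 400, 0.86, rng)
        fit = fit_difference_model(pairs, ADA)
        assert fit.params.beta1 == pytest.approx(23.02, rel=0.05)

    def test_noisy_gada_recovery_within_10_percent(self):
        rng = np.random.default_rng(3)
        pairs = simulate_growth_pairs(GADA, TABLE_GADA, 400, 0.83, rng)
        fit = fit_difference_model(pairs, GADA)
        assert fit.params.beta0 == pytest.approx(534.60, rel=0.10)
        assert fit.params.beta1 == pytest.approx(-144.44, rel=0.10)

    def test_bias_shrinks_with_sample_size(self):
        rng = np.random.default_rng(4)
        bias = []
        for n in (50, 400, 2000):
            est = [
                fit_difference_model(
                    simulate_growth_pairs(ADA, TABLE_ADA, n, 0.86, rng), ADA
                ).params.beta1
                for _ in range(8)
            ]
            bias.append(abs(np.mean(est) - 23.02))
        assert bias[2] < bias[0] + 0.3  # noise allowance on 8 replicates
        assert bias[2] < 0.5

    def test_degenerate_pairs_unidentifiable(self):
        pairs = [GrowthPair("u", 20.0, 20.0, 12.0, 12.0)] * 5
        with pytest.raises(UnidentifiableError):
            fit_difference_model(pairs, ADA)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            fit_difference_model([GrowthPair("u", 20.0, 24.0, 12.0, 13.0)], ADA)

    def test_ada_fit_carries_no_level_parameter(self):
        rng = np.random.default_rng(5)
        fit = fit_difference_model(
            simulate_growth_pairs(ADA, TABLE_ADA, 30, 0.0, rng), ADA
        )
        assert fit.params.beta0 is None


class TestFitPlotHeightModel:
    def test_exact_recovery_from_noiseless_curve(self, noiseless_plot_curve):
        dbh, h = noiseless_plot_curve
        params, stats = fit_plot_height_model((dbh, h))
        assert params.beta0 == pytest.approx(3.4, rel=1e-6)
        assert params.beta1 == pytest.approx(-20.0, rel=1e-6)
        assert stats.r2_adj == pytest.approx(1.0, abs=1e-9)

    def test_single_diameter_design_unidentifiable(self):
        dbh = np.full(10, 25.0)
        h = np.linspace(10, 14, 10)
        with pytest.raises(UnidentifiableError):
            fit_plot_height_model((dbh, h))

    def test_insufficient_trees(self):
        with pytest.raises(InsufficientDataError):
            fit_plot_height_model((np.array([10.0, 20.0, 30.0]),
                                   np.array([5.0, 9.0, 12.0])))

    def test_average_r2_in_calibration_band(self, small_forest):
        # plot-level fits at ~2.86 m height noise should explain a middling
        # share of variance, matching the plot-model regime in mixed stands
        series, _ = small_forest
        r2 = [fit_plot_height_model(s.inventories[0])[1].r2_adj for s in series]
        assert 0.45 <= np.mean(r2) <= 0.75


class TestTwoStageUnitEffects:
    def test_shrinks_toward_pooled_value(self):
        rng = np.random.default_rng(6)
        pairs = simulate_growth_pairs(ADA, TABLE_ADA, 60, 0.5, rng)
        pooled = fit_difference_model(pairs, ADA)
        effects = two_stage_unit_effects(pairs, pooled, shrinkage_n0=20.0)
        # single-pair units: weight 1/21, so estimates hug the pooled value
        spread = np.ptp(list(effects.values()))
        assert spread < 0.5 * abs(pooled.params.beta1)
        assert np.mean(list(effects.values())) == pytest.approx(
            pooled.params.beta1, rel=0.2
        )
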