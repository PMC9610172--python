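import numpy as np
import pytest

from siteform.dominants import TALLEST, dominant_summary, select_dominants
from siteform.errors import InsufficientDataError
from siteform.schumacher import (
    ADA,
    GADA,
    DifferenceModelFit,
    SchumacherParams,
    ada_project,
    fit_statistics,
    schumacher_height,
)
from siteform.site_form import (
    METHOD_HD,
    METHOD_HDBH,
    METHOD_MHMD,
    reference_diameter_profile,
    sf_class_curves,
    site_form_hd,
    site_form_hdbh,
    site_form_mhmd,
)

from conftest import make_series


def _fit(model, unit, beta0, beta1, criterion=TALLEST):
    stats = fit_statistics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], p=1)
    return DifferenceModelFit(
        model=model, unit=unit, criterion=criterion,
        params=SchumacherParams(beta0, beta1), stats=stats,
    )


ADA_TREE = _fit(ADA, "dominant-tree", None, 23.02)
ADA_MEAN = _fit(ADA, "plot-mean", None, 43.34)
GADA_TREE = _fit(GADA, "dominant-tree", 534.60, -144.44)


def _series_with_dominants(rows):
    s = make_series("A", rows)
    dset = select_dominants(s, TALLEST, per_ha=100)
    return s, dset


class TestSiteFormHD:
    def test_identity_when_dominants_at_reference_diameter(self):
        rows = [("t1", 0, 40.0, 18.0), ("t1", 1, 43.0, 19.0),
                ("t2", 0, 40.0, 22.0), ("t2", 1, 44.0, 23.0)]
        s, dset = _series_with_dominants(rows)
        est = site_form_hd(s, 0, dset, ADA_TREE, d_ref=40.0)
        assert est.value == pytest.approx(20.0, abs=1e-12)  # MH of dominants
        assert est.method == METHOD_HD

    def test_single_dominant_matches_projection_oracle(self):
        rows = [("t1", 0, 25.0, 15.0), ("t1", 1, 28.0, 16.0)]
        s, dset = _series_with_dominants(rows)
        est = site_form_hd(s, 0, dset, ADA_TREE, d_ref=40.0)
        assert est.value == pytest.approx(20.65, abs=0.01)

    def test_mean_of_independent_projections(self, small_forest):
        series, _ = small_forest
        s = series[0]
        dset = select_dominants(s, TALLEST)
        est = site_form_hd(s, 0, dset, ADA_TREE, d_ref=40.0)
        obs = {t.tree_id: t for t in s.inventories[0].trees}
        expected = np.mean(
            [ada_project(obs[t].h, obs[t].dbh, 40.0, 23.02) for t in dset.tree_ids]
        )
        assert est.value == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_tree_relabeling_and_order(self):
        rows = [("t1", 0, 25.0, 15.0), ("t1", 1, 28.0, 16.0),
                ("t2", 0, 30.0, 17.0), ("t2", 1, 33.0, 18.0)]
        relabeled = [("zz" + tid, i, d, h) for tid, i, d, h in rows][::-1]
        s1, d1 = _series_with_dominants(rows)
        s2, d2 = _series_with_dominants(relabeled)
        a = site_form_hd(s1, 0, d1, ADA_TREE, 40.0)
        b = site_form_hd(s2, 0, d2, ADA_TREE, 40.0)
        assert a.value == pytest.approx(b.value, rel=1e-14)


class TestSiteFormMHMD:
    def test_identity_when_md_is_reference(self):
        rows = [("t1", 0, 40.0, 18.0), ("t1", 1, 42.0, 19.0)]
        s, dset = _series_with_dominants(rows)
        summary = dominant_summary(dset, s)
        est = site_form_mhmd(summary, 0, ADA_MEAN, d_ref=40.0)
        assert est.value == pytest.approx(18.0, abs=1e-12)
        assert est.method == METHOD_MHMD

    def test_scalar_projection_oracle(self):
        rows = [("t1", 0, 25.0, 18.0), ("t1", 1, 28.0, 19.0)]
        s, dset = _series_with_dominants(rows)
        summary = dominant_summary(dset, s)
        est = site_form_mhmd(summary, 0, ADA_MEAN, d_ref=40.0)
        expected = 1.3 + (18 - 1.3) * np.exp(-43.34 / 40) / np.exp(-43.34 / 25)
        assert est.value == pytest.approx(expected, abs=1e-12)

    def test_jensen_gap_vs_per_tree_projection(self):
        # projecting the mean differs from averaging projections unless the
        # dominants are identical
        mixed = [("t1", 0, 20.0, 14.0), ("t1", 1, 23.0, 15.0),
                 ("t2", 0, 40.0, 22.0), ("t2", 1, 43.0, 23.0)]
        s, dset = _series_with_dominants(mixed)
        summary = dominant_summary(dset, s)
        hd = site_form_hd(s, 0, dset, ADA_TREE, 40.0)
        mhmd = site_form_mhmd(summary, 0, _fit(ADA, "plot-mean", None, 23.02), 40.0)
        assert abs(hd.value - mhmd.value) > 0.05

        same = [("t1", 0, 30.0, 18.0), ("t1", 1, 33.0, 19.0),
                ("t2", 0, 30.0, 18.0), ("t2", 1, 33.0, 19.0)]
        s2, d2 = _series_with_dominants(same)
        summary2 = dominant_summary(d2, s2)
        hd2 = site_form_hd(s2, 0, d2, ADA_TREE, 40.0)
        mhmd2 = site_form_mhmd(summary2, 0, _fit(ADA, "plot-mean", None, 23.02), 40.0)
        assert hd2.value == pytest.approx(mhmd2.value, rel=1e-12)


class TestSiteFormHdbh:
    def test_scalar_oracle(self):
        est = site_form_hdbh("A", 0, SchumacherParams(3.5, -25.0), 40.0)
        assert est.value == pytest.approx(19.03, abs=0.01)
        assert est.method == METHOD_HDBH

    def test_monotone_in_curve_level(self):
        lo = site_form_hdbh("A", 0, SchumacherParams(3.2, -25.0), 40.0)
        hi = site_form_hdbh("B", 0, SchumacherParams(3.6, -25.0), 40.0)
        assert hi.value > lo.value

    def test_identical_params_identical_sf(self):
        p = SchumacherParams(3.3, -20.0)
        assert site_form_hdbh("A", 0, p, 40.0).value == site_form_hdbh(
            "B", 1, p, 40.0
        ).value


class TestReferenceDiameterProfile:
    def test_perfect_predictions_select_smallest(self):
        d = np.repeat([10.0, 20.0, 30.0, 40.0], 5)
        y = np.full_like(d, 15.0)
        profile = reference_diameter_profile(d, y, y, grid=[10, 20, 30, 40])
        assert np.allclose(profile.re[np.isfinite(profile.re)], 0.0)
        assert profile.selected == 10.0

    def test_decreasing_then_flat_profile_selects_knee(self):
        # RE strictly decreasing up to 40 cm, flat plateau beyond: the
        # smallest plateau diameter (40) is the reference diameter
        rng = np.random.default_rng(0)
        grid = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]
        d, y, yhat = [], [], []
        scale = {10: 3.0, 20: 2.0, 30: 1.0, 40: 0.3, 50: 0.3, 60: 0.3}
        for g in grid:
            n = 200
            d.extend([g] * n)
            obs = rng.normal(20.0, 0.01, n)
            y.extend(obs)
            yhat.extend(obs + rng.normal(0, scale[g], n))
        profile = reference_diameter_profile(np.array(d), np.array(y),
                                             np.array(yhat), grid=grid)
        assert profile.selected == 40.0

    def test_single_class(self):
        d = np.full(10, 25.0)
        y = np.linspace(10, 12, 10)
        yhat = y + 0.1
        profile = reference_diameter_profile(d, y, yhat, grid=[25.0])
        assert profile.selected == 25.0

    def test_empty_class_excluded_with_warning(self):
        d = np.full(10, 25.0)
        y = np.linspace(10, 12, 10)
        profile = reference_diameter_profile(d, y, y + 0.1, grid=[25.0, 60.0])
        assert np.isnan(profile.re[1])
        assert profile.selected == 25.0
        assert any("60" in w for w in profile.warnings)


class TestSFClassCurves:
    @staticmethod
    def _plots(levels, rng):
        sf_by_plot, trees_by_plot = {}, {}
        for i, b0 in enumerate(levels):
            pid = f"P{i}"
            dbh = rng.uniform(8, 60, 40)
            h = 1.3 + np.exp(b0 - 20.0 / dbh)
            sf_by_plot[pid] = float(1.3 + np.exp(b0 - 20.0 / 40.0))
            trees_by_plot[pid] = (dbh, h)
        return sf_by_plot, trees_by_plot

    def test_identical_plots_give_identical_class_curves(self):
        rng = np.random.default_rng(1)
        sf, trees = self._plots([3.3] * 6, rng)
        curves = sf_class_curves(sf, trees, n_classes=3)
        b0s = {round(c.params.beta0, 9) for c in curves}
        assert len(b0s) == 1

    def test_class_curves_ordered_on_site_gradient(self):
        rng = np.random.default_rng(2)
        levels = [3.0, 3.05, 3.1, 3.3, 3.35, 3.4, 3.6, 3.65, 3.7]
        sf, trees = self._plots(levels, rng)
        curves = sf_class_curves(sf, trees, n_classes=3)
        at_ref = [schumacher_height(40.0, c.params) for c in curves]
        assert at_ref == sorted(at_ref)
        assert at_ref[0] < at_ref[1] < at_ref[2]

    def test_one_class_equals_pooled_fit(self):
        rng = np.random.default_rng(3)
        sf, trees = self._plots([3.0, 3.4, 3.8], rng)
        curves = sf_class_curves(sf, trees, n_classes=1)
        from siteform.schumacher import fit_plot_height_model

        dbh = np.concatenate([trees[p][0] for p in trees])
        h = np.concatenate([trees[p][1] for p in trees])
        pooled, _ = fit_plot_height_model((dbh, h))
        assert curves[0].params.beta0 == pytest.approx(pooled.beta0, rel=1e-9)

    def test_fewer_plots_than_classes(self):
        rng = np.random.default_rng(4)
        sf, trees = self._plots([3.0, 3.4], rng)
        with pytest.raises(InsufficientDataError):
            sf_class_curves(sf, trees, n_classes=3)


class TestNineVariants:
    def test_complete_plot_period_yields_nine_records(self, small_forest,
                                                      volume_table):
        from siteform.pipeline import run_full_evaluation

        series, _ = small_forest
        bundle = run_full_evaluation(series, volume_table)
        per_period = bundle.sf.groupby(["plot_id", "inventory_index"]).size()
        assert (per_period == 9).all()
        methods = bundle.sf.groupby("method").size()
        n_periods = len(per_period)
        assert methods["SF_H-D"] == 4 * n_periods
        assert methods["SF_MH-MD"] == 4 * n_periods
        assert methods["SF_h-dbh"] == n_periods
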