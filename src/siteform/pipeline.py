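"""End-to-end orchestration: dominants -> fits -> SF -> metrics -> evaluation.

For every plot-period with complete inputs the pipeline produces nine SF
values: SF_H-D and SF_MH-MD each under {ADA, GADA} x {tallest, thickest},
plus SF_h-dbh from the plot-specific curve.  SF for a period is read at the
period's first inventory (site quality going into the growth period), and
is evaluated against that period's PAI and the first inventory's SDI.
Stage failures on individual plots are logged as warnings and the plot is
dropped from the affected variant only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import dominants as dom
from . import evaluate as ev
from .errors import SiteFormError
from .inventory import CoefficientTable, PlotSeries, validate_series
from .schumacher import (
    ADA,
    GADA,
    DifferenceModelFit,
    fit_difference_model,
    fit_plot_height_model,
    plot_mean_growth_pairs,
    tree_growth_pairs,
)
from .site_form import (
    DEFAULT_REFERENCE_DIAMETER,
    SiteFormEstimate,
    reference_diameter_profile,
    site_form_hd,
    site_form_hdbh,
    site_form_mhmd,
)
from .stand import compute_pai, stand_summary

log = logging.getLogger("siteform")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_FITTING = 3


@dataclass
class ResultBundle:
    sf: pd.DataFrame  # long SF table
    stand: pd.DataFrame  # per plot-inventory metrics
    periods: pd.DataFrame  # per plot-period PAI / SDI / conifer proportion
    fits: pd.DataFrame  # difference-model parameter estimates
    correlations: pd.DataFrame  # pooled, per variant x response
    stratified: pd.DataFrame  # mixture-stratified, PAI response
    regressions: pd.DataFrame  # OLS per variant x response
    selected_d_ref: float
    warnings: list[str]
    manifest: dict


def _sf_to_frame(records: list[SiteFormEstimate]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def run_full_evaluation(
    series: list[PlotSeries],
    coefs: CoefficientTable,
    per_ha: float = 100.0,
    d_ref: float | str = DEFAULT_REFERENCE_DIAMETER,
    transform: str = ev.SQRT,
    seed: int | None = None,
) -> ResultBundle:
    """Run the complete SF evaluation over a plot network.

    ``d_ref`` may be a diameter in cm or ``"auto"``, in which case the
    reference diameter is selected from the relative-error profile of the
    tallest-tree ADA model.  Deterministic: identical inputs and settings
    give identical outputs (``seed`` is recorded in the manifest and
    forwarded to no stochastic stage — the analysis itself is exact).
    """
    warnings: list[str] = []
    multi = [s for s in series if s.n_inventories >= 2]
    for s in series:
        if s.n_inventories < 2:
            warnings.append(f"plot {s.plot_id}: single inventory, skipped")
        else:
            report = validate_series(s)
            for issue in report.issues:
                warnings.append(
                    f"plot {issue.plot_id}, tree {issue.tree_id}: "
                    f"{issue.kind} ({issue.detail})"
                )

    # --- dominant sets, summaries and pooled growth pairs ------------------
    dsets: dict[tuple[str, str], dom.DominantSet] = {}
    summaries: dict[tuple[str, str], dom.DominantSummary] = {}
    tree_pairs: dict[str, list] = {c: [] for c in (dom.TALLEST, dom.THICKEST)}
    mean_pairs: dict[str, list] = {c: [] for c in (dom.TALLEST, dom.THICKEST)}
    for s in multi:
        for criterion in (dom.TALLEST, dom.THICKEST):
            try:
                dset = dom.select_dominants(s, criterion, per_ha=per_ha)
                summary = dom.dominant_summary(dset, s)
            except SiteFormError as exc:
                warnings.append(f"plot {s.plot_id} [{criterion}]: {exc}")
                continue
            if dset.shortfall:
                warnings.append(
                    f"plot {s.plot_id} [{criterion}]: only "
                    f"{len(dset.tree_ids)}/{dset.quota} dominants"
                )
            dsets[(s.plot_id, criterion)] = dset
            summaries[(s.plot_id, criterion)] = summary
            tree_pairs[criterion].extend(tree_growth_pairs(s, dset))
            mean_pairs[criterion].extend(plot_mean_growth_pairs(summary))

    # --- the eight difference-model fits -----------------------------------
    fits: dict[tuple[str, str, str], DifferenceModelFit] = {}
    fit_rows = []
    for criterion in (dom.TALLEST, dom.THICKEST):
        for unit, pairs in (
            ("dominant-tree", tree_pairs[criterion]),
            ("plot-mean", mean_pairs[criterion]),
        ):
            for model in (ADA, GADA):
                try:
                    fit = fit_difference_model(pairs, model, unit=unit,
                                               criterion=criterion)
                except SiteFormError as exc:
                    warnings.append(f"{model}/{unit}/{criterion}: {exc}")
                    continue
                fits[(model, unit, criterion)] = fit
                fit_rows.append(
                    dict(
                        model=model, unit=unit, criterion=criterion,
                        beta0=fit.params.beta0, beta1=fit.params.beta1,
                        r2_adj=fit.stats.r2_adj, rmse=fit.stats.rmse,
                        n=fit.stats.n,
                    )
                )

    # --- plot-level h-dbh fits at each period start -------------------------
    plot_fits: dict[tuple[str, int], object] = {}
    for s in multi:
        for i in range(s.n_inventories - 1):
            try:
                params, _stats = fit_plot_height_model(s.inventories[i])
            except SiteFormError as exc:
                warnings.append(f"plot {s.plot_id} [h-dbh @ inv {i}]: {exc}")
                continue
            plot_fits[(s.plot_id, i)] = params

    # --- reference diameter --------------------------------------------------
    if d_ref == "auto":
        key = (ADA, "dominant-tree", dom.TALLEST)
        if key not in fits:
            raise SiteFormError("cannot auto-select d_ref: tallest ADA fit failed")
        fit = fits[key]
        pairs = tree_pairs[dom.TALLEST]
        from .schumacher import ada_project

        d2 = np.array([p.d2 for p in pairs])
        obs = np.array([p.h2 for p in pairs])
        pred = ada_project(
            np.array([p.h1 for p in pairs]),
            np.array([p.d1 for p in pairs]),
            d2,
            fit.params.beta1,
        )
        profile = reference_diameter_profile(d2, obs, pred, p=1)
        warnings.extend(profile.warnings)
        selected_d_ref = profile.selected
    else:
        selected_d_ref = float(d_ref)

    # --- nine SF values per plot-period -------------------------------------
    sf_records: list[SiteFormEstimate] = []
    for s in multi:
        for i in range(s.n_inventories - 1):
            for criterion in (dom.TALLEST, dom.THICKEST):
                dset = dsets.get((s.plot_id, criterion))
                summary = summaries.get((s.plot_id, criterion))
                for model in (ADA, GADA):
                    fit_t = fits.get((model, "dominant-tree", criterion))
                    if dset is not None and fit_t is not None:
                        try:
                            sf_records.append(
                                site_form_hd(s, i, dset, fit_t, selected_d_ref)
                            )
                        except SiteFormError as exc:
                            warnings.append(
                                f"plot {s.plot_id} [SF_H-D {model}/{criterion}]: {exc}"
                            )
                    fit_m = fits.get((model, "plot-mean", criterion))
                    if summary is not None and fit_m is not None:
                        try:
                            sf_records.append(
                                site_form_mhmd(summary, i, fit_m, selected_d_ref)
                            )
                        except SiteFormError as exc:
                            warnings.append(
                                f"plot {s.plot_id} [SF_MH-MD {model}/{criterion}]: {exc}"
                            )
            params = plot_fits.get((s.plot_id, i))
            if params is not None:
                try:
                    sf_records.append(
                        site_form_hdbh(s.plot_id, i, params, selected_d_ref)
                    )
                except SiteFormError as exc:
                    warnings.append(f"plot {s.plot_id} [SF_h-dbh]: {exc}")
    sf_df = _sf_to_frame(sf_records)

    # --- stand metrics and per-period responses -----------------------------
    stand_rows = []
    period_rows = []
    for s in multi:
        metrics = {}
        for inv in s.inventories:
            try:
                m = stand_summary(inv, coefs)
            except SiteFormError as exc:
                warnings.append(f"plot {s.plot_id} [metrics @ inv "
                                f"{inv.inventory_index}]: {exc}")
                continue
            metrics[inv.inventory_index] = m
            stand_rows.append(dataclasses.asdict(m))
        for i in range(s.n_inventories - 1):
            if i not in metrics:
                continue
            try:
                pai = compute_pai(s, (i, i + 1), coefs)
            except SiteFormError as exc:
                warnings.append(f"plot {s.plot_id} [PAI {i}->{i + 1}]: {exc}")
                continue
            m = metrics[i]
            period_rows.append(
                dict(
                    plot_id=s.plot_id,
                    inventory_index=i,
                    pai=pai,
                    sdi=m.sdi,
                    conifer_prop=m.conifer_prop,
                )
            )
    stand_df = pd.DataFrame(stand_rows)
    period_df = pd.DataFrame(period_rows)

    # --- evaluation ----------------------------------------------------------
    corr_rows, strat_rows, regr_rows = [], [], []
    if not sf_df.empty and not period_df.empty:
        merged = sf_df.merge(period_df, on=["plot_id", "inventory_index"])
        for (method, model, criterion), grp in merged.groupby(
            ["method", "model", "criterion"], sort=True
        ):
            variant = dict(method=method, model=model, criterion=criterion)
            for response in ("pai", "sdi"):
                resp = grp[response].to_numpy()
                if np.any(resp < 0):
                    resp = np.clip(resp, 0.0, None)
                try:
                    c = ev.correlate_sf_response(
                        grp["value"].to_numpy(), resp, transform=transform
                    )
                    r = ev.regress_sf_response(
                        grp["value"].to_numpy(), resp, transform=transform
                    )
                except SiteFormError as exc:
                    warnings.append(
                        f"evaluation {method}/{model}/{criterion}/{response}: {exc}"
                    )
                    continue
                corr_rows.append(
                    {**variant, "response": response, "n": c.n,
                     "r_pearson": c.r_pearson, "p_value": c.p_value}
                )
                regr_rows.append(
                    {**variant, "response": response, "n": r.n,
                     "intercept": r.intercept, "slope": r.slope,
                     "intercept_ns": r.intercept_ns, "slope_ns": r.slope_ns,
                     "r2_adj": r.r2_adj, "rmse": r.rmse,
                     "shapiro_w": r.shapiro_w, "shapiro_p": r.shapiro_p}
                )
            for stratum, res in ev.stratified_correlations(
                grp["value"].to_numpy(),
                np.clip(grp["pai"].to_numpy(), 0.0, None),
                grp["conifer_prop"].to_numpy(),
                transform=transform,
            ):
                strat_rows.append(
                    {**variant, "stratum": stratum.label, "n": res.n,
                     "r_pearson": res.r_pearson, "p_value": res.p_value,
                     "available": res.available}
                )

    manifest = dict(
        settings=dict(
            per_ha=per_ha,
            d_ref="auto" if d_ref == "auto" else float(d_ref),
            selected_d_ref=selected_d_ref,
            transform=transform,
            seed=seed,
        ),
        counts=dict(
            plots=len(series),
            plots_analyzed=len(multi),
            sf_records=len(sf_records),
            plot_periods=sum(s.n_inventories - 1 for s in multi),
            difference_fits=len(fits),
            warnings=len(warnings),
        ),
        warnings=warnings,
    )
    return ResultBundle(
        sf=sf_df,
        stand=stand_df,
        periods=period_df,
        fits=pd.DataFrame(fit_rows),
        correlations=pd.DataFrame(corr_rows),
        stratified=pd.DataFrame(strat_rows),
        regressions=pd.DataFrame(regr_rows),
        selected_d_ref=selected_d_ref,
        warnings=warnings,
        manifest=manifest,
    )


def write_bundle(bundle: ResultBundle, out_dir: str | Path) -> None:
    """Write the result bundle as tidy CSVs plus a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.sf.to_csv(out / "site_form.csv", index=False)
    bundle.stand.to_csv(out / "stand_metrics.csv", index=False)
    bundle.periods.to_csv(out / "plot_periods.csv", index=False)
    bundle.fits.to_csv(out / "difference_fits.csv", index=False)
    bundle.correlations.to_csv(out / "correlations.csv", index=False)
    bundle.stratified.to_csv(out / "stratified_correlations.csv", index=False)
    bundle.regressions.to_csv(out / "regressions.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)
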