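"""End-to-end orchestration: simulate -> thermal -> ETo/irrigation -> fit ->
indices -> stats, writing every intermediate table plus a run manifest.

All randomness flows from one root seed through named substreams per stage,
so a manifest-recorded seed reproduces every output byte for byte.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chiagrow.dlogistic import (
    TABLE_COLUMNS,
    average_coefficients,
    compare_fits,
    fit_double_logistic,
)
from chiagrow.eto import eto_series, irrigation_to_frame, schedule_irrigation, season_water_total
from chiagrow.fieldstats import correlation_matrix, duncan_mrt, one_way_anova
from chiagrow.indices import functional_indices, interval_indices
from chiagrow.synth import TrialDesign, generate_plant_data, generate_weather, irrigation_design, sowing_date_design
from chiagrow.weather import accumulate_gdd, stage_table, weather_to_frame

log = logging.getLogger("chiagrow.pipeline")

_STAGE_SEEDS = {"weather": 11, "plants": 23, "fit": 37}


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    ``trial`` selects the built-in design ("sowing_date" or "irrigation");
    irrigation fractions apply to the irrigation trial's scheduler.
    """

    trial: str = "sowing_date"
    seed: int = 0
    outdir: str | Path = "results/pipeline"
    tbase: float = 10.0
    trigger_mm: float = 8.0
    fractions: tuple[float, ...] = (1.0, 0.4)
    clamp_negative_eto: bool = True
    time_axis: str = "add"
    restarts: int = 5
    design: TrialDesign | None = None  # overrides ``trial`` when given

    def resolve_design(self) -> TrialDesign:
        if self.design is not None:
            return self.design
        if self.trial == "sowing_date":
            return sowing_date_design()
        if self.trial == "irrigation":
            return irrigation_design()
        raise ValueError(f"unknown trial {self.trial!r}")


def _substream(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, _STAGE_SEEDS[stage]]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write the result bundle.

    Returns a dict of the in-memory stage outputs (weather frame, thermal
    series, fits, tables); the same content is written as CSV/JSON under
    ``config.outdir``.  Idempotent for a fixed seed.
    """
    design = config.resolve_design()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"design": design}

    # --- weather: one series per site, covering every treatment's season
    first_sowing = min(t.sowing_date for t in design.treatments)
    last_day = max(
        t.sowing_date + dt.timedelta(days=design.season_days) for t in design.treatments
    )
    n_days = (last_day - first_sowing).days + 1
    weather = generate_weather(
        design.site, first_sowing, n_days, seed=_substream(config.seed, "weather")
    )
    wframe = weather_to_frame(weather)
    wframe.to_csv(outdir / "weather.csv", index=False)
    bundle["weather"] = weather
    log.info("weather: %d days at %s", n_days, design.site.name)

    # --- thermal time per treatment (each from its own sowing date)
    thermal = {}
    phen_rows = []
    for trt in design.treatments:
        series = accumulate_gdd(weather, tbase=config.tbase, start_date=trt.sowing_date)
        thermal[trt.label] = series
        series.to_frame().to_csv(outdir / f"thermal_{trt.label}.csv", index=False)
        if trt.stage_das:
            for rec in stage_table(series, trt.stage_das):
                phen_rows.append(
                    {"treatment": trt.label, "stage": rec.stage, "das": rec.das, "add": rec.add}
                )
    bundle["thermal"] = thermal
    if phen_rows:
        pd.DataFrame(phen_rows).to_csv(outdir / "phenology.csv", index=False)
        bundle["phenology"] = pd.DataFrame(phen_rows)

    # --- ETo and (for the irrigation trial) the dosing schedule
    eto = eto_series(weather, clamp_negative=False)
    eto.to_csv(outdir / "eto.csv", index=False)
    bundle["eto"] = eto
    if design.name == "irrigation":
        start = design.treatments[0].sowing_date + dt.timedelta(
            days=design.treatments[0].start_das
        )
        season_end = design.treatments[0].sowing_date + dt.timedelta(days=design.season_days)
        window = eto[(pd.to_datetime(eto["date"]).dt.date >= start)
                     & (pd.to_datetime(eto["date"]).dt.date <= season_end)]
        totals = {}
        for frac in config.fractions:
            events = schedule_irrigation(
                list(window["date"]), list(window["eto_mm"]), fraction=frac,
                trigger=config.trigger_mm, clamp_negative=config.clamp_negative_eto,
            )
            tag = f"{int(round(100 * frac))}"
            irrigation_to_frame(events, frac).to_csv(
                outdir / f"irrigation_{tag}pct.csv", index=False
            )
            totals[frac] = season_water_total(events)
        bundle["irrigation_totals"] = totals
        log.info("irrigation totals (L m^-2): %s", totals)

    # --- synthetic harvests
    plants = generate_plant_data(design, thermal, seed=_substream(config.seed, "plants"))
    plants.to_csv(outdir / "plants.csv", index=False)
    bundle["plants"] = plants

    # --- double-logistic fits per treatment and variable, on harvest means
    plants = plants.assign(
        dm_total_g=plants[["dm_leaf_g", "dm_stem_g", "dm_root_g", "dm_inflo_g"]].sum(axis=1)
    )
    fit_seed = _substream(config.seed, "fit")
    fits: dict[tuple[str, str], object] = {}
    coef_rows = {}
    for variable, column in (("biomass", "dm_total_g"), ("leaf_area", "leaf_area_cm2")):
        for i, trt in enumerate(design.treatments):
            sub = plants[plants["treatment"] == trt.label]
            means = sub.groupby("das").agg({column: "mean", "add": "first"}).reset_index()
            t = means["add" if config.time_axis == "add" else "das"].to_numpy(dtype=float)
            fit = fit_double_logistic(
                t, means[column].to_numpy(), restarts=config.restarts,
                seed=fit_seed + i, variable=variable,
            )
            fits[(variable, trt.label)] = fit
            coef_rows[(variable, trt.label)] = fit.to_row()
            log.info("fit %s %s: R2=%.4f rmse=%.4g", variable, trt.label, fit.r2, fit.rmse)
    coef_table = pd.DataFrame(coef_rows).T
    coef_table.index.names = ["variable", "treatment"]
    # trial-average rows and the paired-t comparison of the two fits
    comparisons = []
    for variable in ("biomass", "leaf_area"):
        rows = [coef_rows[(variable, t.label)] for t in design.treatments]
        avg = average_coefficients(rows)
        coef_table.loc[(variable, "Average"), :] = avg[TABLE_COLUMNS].to_numpy()
        fa = fits[(variable, design.treatments[0].label)]
        fb = fits[(variable, design.treatments[1].label)]
        comparisons.append(
            {"variable": variable,
             "pair": f"{design.treatments[0].label}-{design.treatments[1].label}",
             "p_paired_t": compare_fits(fa, fb)}
        )
    coef_table.reset_index().to_csv(outdir / "coefficients.csv", index=False)
    pd.DataFrame(comparisons).to_csv(outdir / "fit_comparisons.csv", index=False)
    bundle["fits"] = fits
    bundle["coefficients"] = coef_table
    bundle["fit_comparisons"] = pd.DataFrame(comparisons)

    # --- growth indices: interval (Hunt) and functional (fitted curves)
    interval_frames = []
    functional_frames = []
    for trt in design.treatments:
        sub = plants[plants["treatment"] == trt.label]
        iv = interval_indices(
            sub[["treatment", "block", "plant_id", "das", "leaf_area_cm2",
                 "dm_leaf_g", "dm_stem_g", "dm_root_g", "dm_inflo_g"]],
            density=trt.density, thermal=thermal[trt.label],
        )
        interval_frames.append(iv)
        series = thermal[trt.label]
        fb = fits[("biomass", trt.label)]
        fl = fits[("leaf_area", trt.label)]
        add_lo = float(series.das_to_add(float(design.first_harvest_das)))
        add_hi = float(series.das_to_add(float(design.harvest_das()[-1])))
        grid = np.linspace(add_lo, add_hi, 101)
        add_per_day = (add_hi - add_lo) / (design.harvest_das()[-1] - design.first_harvest_das)
        leaf_frac = sub.groupby("das").apply(
            lambda g: g["dm_leaf_g"].sum() / g[["dm_leaf_g", "dm_stem_g", "dm_root_g", "dm_inflo_g"]].sum().sum(),
            include_groups=False,
        ).mean()
        try:
            fi = functional_indices(
                fb, fl, density=trt.density, t_grid=grid,
                leaf_fraction=float(leaf_frac), add_per_day=add_per_day,
            )
            fi.insert(0, "treatment", trt.label)
            functional_frames.append(fi)
        except ValueError as exc:  # fitted biomass curve dips <= 0 on the grid
            log.warning("functional indices skipped for %s: %s", trt.label, exc)
    interval_table = pd.concat(interval_frames, ignore_index=True)
    interval_table.to_csv(outdir / "indices_interval.csv", index=False)
    bundle["indices_interval"] = interval_table
    if functional_frames:
        functional_table = pd.concat(functional_frames, ignore_index=True)
        functional_table.to_csv(outdir / "indices_functional.csv", index=False)
        bundle["indices_functional"] = functional_table

    # --- per-harvest ANOVA + Duncan letters on plot means; correlations
    stats_rows = []
    letter_rows = []
    for response in ("dm_total_g", "leaf_area_cm2"):
        for das, grp in plants.groupby("das"):
            plot_means = grp.groupby(["treatment", "block"])[response].mean().reset_index()
            groups = {
                t: plot_means.loc[plot_means["treatment"] == t, response].to_numpy()
                for t in plot_means["treatment"].unique()
            }
            if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
                continue
            table = one_way_anova(list(groups.values()))
            stats_rows.append(
                {"response": response, "das": das, "df_trt": table.df[0],
                 "df_err": table.df[1], "F": table.f, "p": table.p}
            )
            if np.isfinite(table.f) and table.p < 0.05:
                dr = duncan_mrt(groups, alpha=0.05)
                for lab, mean, letters in zip(dr.labels, dr.means, dr.letters):
                    letter_rows.append(
                        {"response": response, "das": das, "treatment": lab,
                         "mean": mean, "letters": letters}
                    )
    pd.DataFrame(stats_rows).to_csv(outdir / "anova.csv", index=False)
    if letter_rows:
        pd.DataFrame(letter_rows).to_csv(outdir / "duncan_letters.csv", index=False)
    bundle["anova"] = pd.DataFrame(stats_rows)

    corr_frames = []
    for trt in design.treatments:
        iv = interval_table[interval_table["treatment"] == trt.label]
        r, p = correlation_matrix(iv[["rgr", "nar", "lar", "slw", "cgr"]])
        r = r.assign(treatment=trt.label, index=r.index)
        corr_frames.append(r)
        bundle[f"correlation_{trt.label}"] = (r, p)
    pd.concat(corr_frames, ignore_index=True).to_csv(outdir / "correlations.csv", index=False)

    from chiagrow import __version__
    manifest = {
        "package_version": __version__,
        "trial": design.name,
        "seed": config.seed,
        "tbase": config.tbase,
        "trigger_mm": config.trigger_mm,
        "fractions": list(config.fractions),
        "time_axis": config.time_axis,
        "restarts": config.restarts,
        "n_treatments": len(design.treatments),
        "n_blocks": design.n_blocks,
        "n_plants_per_harvest": design.n_plants_per_harvest,
        "harvest_das": design.harvest_das(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    bundle["manifest"] = manifest
    return bundle
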