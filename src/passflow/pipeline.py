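"""End-to-end orchestration: simulate/load, classify, scale, model, report.

A run is a pure function of (inputs, config, master seed).  Each stage's
outputs are written as delimited tables under the output directory and a
JSON manifest records the config snapshot, seeds, stage statuses and output
paths; identical manifests imply identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bioflow, classify, io as pio, massdays, sunlight, synthetic
from . import weather as wm
from .config import PipelineConfig, SimConfig

__all__ = ["run_pipeline"]

STAGES = ("simulate", "classify", "bioflow", "massdays", "weathermodel",
          "sunlight", "report")


def _hash_config(pipe: PipelineConfig, sim: SimConfig) -> str:
    blob = json.dumps({"pipeline": asdict(pipe), "simulation": {
        **asdict(sim),
        "zinb_params": asdict(sim.zinb_params),
        "taxon_profiles": [asdict(p) for p in sim.taxon_profiles],
    }}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(paths: dict) -> dict:
    required = ("trap", "video", "visual", "weather")
    missing = [k for k in required if k not in paths
               or not Path(paths[k]).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing input tables: {missing}; files mode needs all of "
            f"{required}")
    tables = {k: pio.read_table(paths[k], k) for k in required}
    return tables


def run_pipeline(pipe: PipelineConfig = None, sim: SimConfig = None,
                 mode: str = "synthetic", input_paths: dict = None,
                 seed: int = None, out_dir="pipeline_out") -> dict:
    """Run all stages in dependency order and write tables plus a report.

    In ``synthetic`` mode a full season is generated from ``sim``; in
    ``files`` mode the four input tables are read from ``input_paths``.
    Returns the manifest dict (also written as ``manifest.json``).  A stage
    failure is recorded and dependent stages are skipped.
    """
    pipe = pipe or PipelineConfig()
    sim = sim or SimConfig()
    if seed is not None:
        sim.rng_seed = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "mode": mode,
        "master_seed": sim.rng_seed,
        "config_hash": _hash_config(pipe, sim),
        "stages": {},
        "outputs": {},
    }
    report_lines = [f"passflow run (mode={mode}, seed={sim.rng_seed}, "
                    f"config {manifest['config_hash']})", ""]

    def record(stage, status, detail=""):
        manifest["stages"][stage] = {"status": status, "detail": detail}

    # --- stage: obtain data ----------------------------------------------
    try:
        if mode == "synthetic":
            tables = synthetic.simulate_season(
                sim, missed_fraction=pipe.missed_fraction)
        elif mode == "files":
            tables = _load_inputs(input_paths or {})
            tables["weather"] = wm.derive_covariates(
                tables["weather"], pipe.headwind_bearing_deg,
                pipe.sunshine_window_min)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for name in ("trap", "video", "visual", "weather"):
            path = out / f"{name}.tsv"
            pio.write_table(tables[name], path, name)
            manifest["outputs"][name] = str(path)
        record("simulate", "ok", f"{len(tables['weather'])} days")
    except Exception as exc:  # noqa: BLE001 - manifest records the failure
        record("simulate", "failed", str(exc))
        for s in STAGES[1:]:
            record(s, "skipped", "upstream failure")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    # --- classification ---------------------------------------------------
    try:
        pipe_cls = pipe
        if not pipe.taxon_orders and mode == "synthetic":
            pipe_cls = PipelineConfig(**{**asdict(pipe), "taxon_orders": {
                p.taxon: p.order for p in sim.taxon_profiles}})
        cls = classify.classify_assemblage(tables["trap"],
                                           tables["weather"], pipe_cls)
        cls["classes"].to_csv(out / "classification.tsv", sep="\t",
                              index=False)
        manifest["outputs"]["classification"] = str(out / "classification.tsv")
        record("classify", "ok",
               cls["classes"]["category"].value_counts().to_dict())
        report_lines += ["## Migrant classification",
                         cls["classes"].to_string(index=False), ""]
        if len(cls["order_percent"]):
            report_lines += ["Migratory composition by order (%):",
                             cls["order_percent"].round(1).to_string(), ""]
    except Exception as exc:  # noqa: BLE001
        record("classify", "failed", str(exc))
        cls = None

    # --- bioflow ----------------------------------------------------------
    try:
        taxon_counts = tables["trap"].groupby("taxon")["count"].sum()
        pipe_bf = pipe
        if not pipe.mass_table and mode == "synthetic":
            pipe_bf = PipelineConfig(**{**asdict(pipe), "mass_table": {
                p.taxon: p.mass_mg for p in sim.taxon_profiles}})
        summary = bioflow.season_totals(tables["video"], tables["visual"],
                                        pipe_bf, taxon_counts=taxon_counts)
        summary.per_season.to_csv(out / "season_totals.tsv", sep="\t")
        manifest["outputs"]["season_totals"] = str(out / "season_totals.tsv")
        bioflow.mtr_table(tables["video"]).to_csv(
            out / "mtr.tsv", sep="\t", index=False)
        manifest["outputs"]["mtr"] = str(out / "mtr.tsv")
        record("bioflow", "ok", f"mean total {summary.mean_total:.3g}")
        report_lines += [
            "## Seasonal bioflow",
            summary.per_season.round(1).to_string(),
            f"mean seasonal total: {summary.mean_total:,.0f} individuals",
            f"fold variation: {summary.fold_variation:.1f}", ""]
        if "sexed" in tables:
            for _, row in tables["sexed"].iterrows():
                frac, n = bioflow.sex_ratio(row["n_female"], row["n"])
                report_lines.append(
                    f"sex ratio {row['taxon']}: F {100 * frac:.0f}% (n={n})")
            report_lines.append("")
    except Exception as exc:  # noqa: BLE001
        record("bioflow", "failed", str(exc))

    # --- mass-migration days ---------------------------------------------
    daily = None
    try:
        daily = bioflow.integrated_daily_totals(tables["video"],
                                                tables["visual"], pipe)
        sel = massdays.select_mass_days(daily, pipe.cumulative_mass_fraction)
        prof = massdays.diurnal_profile(tables["video"],
                                        sel.selected_days["date"])
        sel.selected_days.to_csv(out / "mass_days.tsv", sep="\t", index=False)
        prof["profile"].to_csv(out / "diurnal_profile.tsv", sep="\t")
        manifest["outputs"]["mass_days"] = str(out / "mass_days.tsv")
        manifest["outputs"]["diurnal_profile"] = str(
            out / "diurnal_profile.tsv")
        record("massdays", "ok", f"{sel.n_selected} days, "
                                 f"peak {prof['peak_bin']}")
        report_lines += [
            "## Mass migration",
            f"{sel.n_selected} mass-migration days reach "
            f"{100 * sel.cumulative_fraction_at_cut:.1f}% of the total",
            f"diurnal peak bin: {prof['peak_bin']} "
            f"(over {prof['n_days']} days)", ""]
    except Exception as exc:  # noqa: BLE001
        record("massdays", "failed", str(exc))

    # --- weather model ----------------------------------------------------
    try:
        if daily is None:
            raise RuntimeError("no daily totals (massdays stage failed)")
        data = tables["weather"].merge(daily, on="date", how="left")
        data["total_count"] = data["total_count"].fillna(0).astype(np.int64)
        count_terms = [t for t in sim.zinb_params.beta if t != "intercept"]
        zero_terms = [t for t in sim.zinb_params.gamma if t != "intercept"]
        fit = wm.fit_zinb_terms(data, count_terms, zero_terms)
        coefs = fit.coef_table()
        coefs.to_csv(out / "zinb_coefficients.tsv", sep="\t")
        manifest["outputs"]["zinb_coefficients"] = str(
            out / "zinb_coefficients.tsv")
        record("weathermodel", "ok", f"AIC {fit.aic:.1f}")
        report_lines += [
            "## Weather model (ZINB, cauchit zero link)",
            f"theta = {fit.theta:.3f}, logLik = {fit.loglik:.2f}, "
            f"AIC = {fit.aic:.1f}, converged = {fit.converged}",
            coefs.round(3).to_string(), ""]
    except Exception as exc:  # noqa: BLE001
        record("weathermodel", "failed", str(exc))

    # --- sunlight ---------------------------------------------------------
    try:
        if mode == "synthetic":
            occ = synthetic.simulate_sun_occasions(
                382, sim.sun_fold, seed=sim.rng_seed,
                shade_mean=sim.sun_shade_mean, theta=sim.sun_theta,
                p_sun=sim.sun_p_present)
        else:
            vid = tables["video"]
            if "sun_present" not in vid.columns or vid["sun_present"].isna().all():
                raise ValueError("video table lacks sun_present labels")
            occ = vid.rename(columns={})[["sun_present", "count"]]
        cmp_ = sunlight.sun_presence_test(occ)
        lines = ["## Sunlight",
                 f"sun/shade fold = {cmp_.fold:.1f} "
                 f"(t = {cmp_.t_stat:.2f}, df = {cmp_.df:.0f}, "
                 f"p = {cmp_.p_value:.2g})"]
        if "sun_percent" in tables["visual"].columns and \
                tables["visual"]["sun_percent"].notna().sum() >= 3:
            lin = sunlight.sun_linear_fit(tables["visual"])
            lines.append(
                f"visual counts ~ %sun: R^2 = {lin.r_squared:.3f}, "
                f"F(1,{lin.df_den}) = {lin.f_stat:.2f}, "
                f"p = {lin.p_value:.2g}")
        record("sunlight", "ok", f"fold {cmp_.fold:.2f}")
        report_lines += lines + [""]
    except Exception as exc:  # noqa: BLE001
        record("sunlight", "failed", str(exc))

    report = "\n".join(report_lines) + "\n"
    (out / "report.txt").write_text(report)
    manifest["outputs"]["report"] = str(out / "report.txt")
    record("report", "ok")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    manifest["outputs"]["manifest"] = str(out / "manifest.json")
    return manifest
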