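"""Scaling raw counts to pass-level bioflows and seasonal budgets.

Two count streams cover the 30 m pass.  Large insects (butterflies,
dragonflies) are counted visually over the full width for 15 min every 2 h;
multiplying a count ``N1`` by 8 extrapolates it to its 2-h block.  Small
insects come from 1-min videos of a 2 m strip every 15 min; a raw count
``N2`` scales by 15 (time) x 15 (width) = 225 to a pass-level 15-min total.
Because 57% of migratory individuals are below the camera's resolution
limit, video-derived totals are further inflated by 1/(1-0.57).

The migratory traffic rate MTR = count / (duration x width) expresses any
count as individuals per metre of front per minute, comparable across
protocols and sites.

Seasonal budgets sum the scaled streams per season and convert counts to
biomass via a per-taxon mass table, and biomass to nitrogen/phosphorus flux
via configurable elemental fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = ["scale_bihourly", "scale_video", "mtr", "correct_missed",
           "season_totals", "sex_ratio", "role_percentages",
           "historical_comparison", "mtr_table", "SeasonSummary"]

BIHOURLY_FACTOR = 8      # 15 min -> 2 h
VIDEO_TIME_FACTOR = 15   # 1 min -> 15 min
VIDEO_WIDTH_FACTOR = 15  # 2 m -> 30 m


def scale_bihourly(n1):
    """Extrapolate a 15-min full-width count to its 2-h block (x8)."""
    n1 = np.asarray(n1)
    if np.any(n1 < 0):
        raise ValueError("counts must be non-negative")
    out = BIHOURLY_FACTOR * n1
    return out.item() if out.ndim == 0 else out


def scale_video(n2):
    """Scale a raw 1-min, 2-m video count to the 15-min, 30-m pass (x225)."""
    n2 = np.asarray(n2)
    if np.any(n2 < 0):
        raise ValueError("counts must be non-negative")
    out = VIDEO_TIME_FACTOR * VIDEO_WIDTH_FACTOR * n2
    return out.item() if out.ndim == 0 else out


def mtr(count, duration_min, width_m):
    """Migratory traffic rate: individuals per metre of front per minute."""
    if np.any(np.asarray(duration_min) <= 0) or np.any(np.asarray(width_m) <= 0):
        raise ValueError("duration and width must be positive")
    if np.any(np.asarray(count) < 0):
        raise ValueError("counts must be non-negative")
    out = np.asarray(count) / (np.asarray(duration_min) * np.asarray(width_m))
    return out.item() if out.ndim == 0 else out


def correct_missed(total_visible, missed_fraction: float = 0.57):
    """Inflate a visible total for individuals below camera resolution.

    With a fraction ``f`` of individuals unresolvable, the visible total is
    a binomial thinning at rate ``1-f``; dividing by ``1-f`` is the
    unbiased inverse.  Returns the nearest integer.
    """
    if not 0 <= missed_fraction < 1:
        raise ValueError("missed_fraction must lie in [0, 1)")
    if np.any(np.asarray(total_visible) < 0):
        raise ValueError("counts must be non-negative")
    out = np.rint(np.asarray(total_visible, dtype=float)
                  / (1.0 - missed_fraction)).astype(np.int64)
    return out.item() if out.ndim == 0 else out


def mtr_table(video: pd.DataFrame) -> pd.DataFrame:
    """Per-bin MTR (m^-1 min^-1) from raw video counts."""
    out = video.copy()
    out["mtr"] = mtr(out["count"].to_numpy(),
                     out["duration_min"].to_numpy(),
                     out["width_m"].to_numpy())
    return out


@dataclass
class SeasonSummary:
    per_season: pd.DataFrame
    mean_total: float
    fold_variation: float  # max/min across seasons, 1 dp at report time
    grand_total: float


def _season_of(ts: pd.Series) -> pd.Series:
    return pd.to_datetime(ts).dt.year


def season_totals(video: pd.DataFrame, visual: pd.DataFrame,
                  config: PipelineConfig = None,
                  taxon_counts: pd.Series = None) -> SeasonSummary:
    """Per-season scaled totals, fold variation and biomass/nutrient flux.

    Video counts are scaled x225 and corrected for missed insects; visual
    counts are scaled x8.  Seasons with no records are dropped with a
    warning column rather than an error.  Biomass uses ``taxon_counts``
    (counts per identified taxon) against ``config.mass_table`` where
    available, with video individuals otherwise priced at the table's
    ``_video_mean_mg`` entry.
    """
    config = config or PipelineConfig()
    rows = {}
    vid = video.copy()
    vid["season"] = _season_of(vid["timestamp"])
    for season, grp in vid.groupby("season"):
        scaled = float(scale_video(grp["count"].to_numpy()).sum())
        corrected = scaled / (1.0 - config.missed_fraction)
        rows.setdefault(season, {})["video_total"] = corrected
    vis = visual.copy()
    if len(vis):
        vis["season"] = _season_of(vis["timestamp"])
        for season, grp in vis.groupby("season"):
            rows.setdefault(season, {})["visual_total"] = float(
                scale_bihourly(grp["count"].to_numpy()).sum())
    per = (pd.DataFrame.from_dict(rows, orient="index")
           .fillna(0.0).sort_index())
    per.index.name = "season"
    if "visual_total" not in per.columns:
        per["visual_total"] = 0.0
    per["total"] = per["video_total"] + per["visual_total"]
    per = per[per["total"] > 0]
    if per.empty:
        raise ValueError("no season has any records")

    mean_total = float(per["total"].mean())
    fold = float(per["total"].max() / per["total"].min())

    # price pass-level totals at the mean per-individual mass; the
    # identified catch supplies the composition when available
    mean_mg = config.mass_table.get("_video_mean_mg", 10.0)
    if taxon_counts is not None and len(taxon_counts) \
            and float(taxon_counts.sum()) > 0:
        mean_mg = float(sum(
            cnt * config.mass_table.get(taxon, mean_mg)
            for taxon, cnt in taxon_counts.items())) / float(
                taxon_counts.sum())
    biomass_kg = float(per["total"].sum()) * mean_mg / 1e6
    per_season_biomass = biomass_kg * per["total"] / per["total"].sum()
    per["biomass_kg"] = per_season_biomass
    per["nitrogen_kg"] = config.nitrogen_fraction * per["biomass_kg"]
    per["phosphorus_kg"] = config.phosphorus_fraction * per["biomass_kg"]
    return SeasonSummary(per_season=per, mean_total=mean_total,
                         fold_variation=fold,
                         grand_total=float(per["total"].sum()))


def integrated_daily_totals(video: pd.DataFrame, visual: pd.DataFrame,
                            config: PipelineConfig = None,
                            correct: bool = True) -> pd.DataFrame:
    """Pass-level daily totals combining both count streams.

    Per day: video counts scaled x225 (missed-insect corrected unless
    ``correct`` is off) plus visual counts scaled x8.  Returns ``date,
    total_count`` for every day with any record.
    """
    config = config or PipelineConfig()
    vid = video.copy()
    vid["date"] = pd.to_datetime(vid["timestamp"]).dt.normalize()
    day_video = vid.groupby("date")["count"].sum().astype(float) * (
        VIDEO_TIME_FACTOR * VIDEO_WIDTH_FACTOR)
    if correct:
        day_video = day_video / (1.0 - config.missed_fraction)
    parts = [day_video]
    if visual is not None and len(visual):
        vis = visual.copy()
        vis["date"] = pd.to_datetime(vis["timestamp"]).dt.normalize()
        parts.append(vis.groupby("date")["count"].sum().astype(float)
                     * BIHOURLY_FACTOR)
    total = pd.concat(parts, axis=1).fillna(0.0).sum(axis=1)
    out = total.round().astype(np.int64).rename("total_count").reset_index()
    return out


def sex_ratio(n_female: int, n_total: int):
    """Female fraction with its sample size; undefined (None) at n=0."""
    if n_total < 0 or n_female < 0 or n_female > n_total:
        raise ValueError("need 0 <= n_female <= n_total")
    if n_total == 0:
        return None, 0
    return n_female / n_total, int(n_total)


def role_percentages(taxon_counts: pd.Series, roles_table: dict) -> pd.Series:
    """Percentage of individuals per ecological role (roles may overlap)."""
    missing = [t for t in taxon_counts.index if t not in roles_table]
    if missing:
        raise KeyError(f"taxa missing from roles table: {missing}")
    total = float(taxon_counts.sum())
    if total <= 0:
        raise ValueError("no individuals counted")
    all_roles = sorted({r for roles in roles_table.values() for r in roles})
    out = {}
    for role in all_roles:
        n = sum(cnt for taxon, cnt in taxon_counts.items()
                if role in roles_table[taxon])
        out[role] = 100.0 * n / total
    return pd.Series(out).sort_values(ascending=False)


def historical_comparison(mean_scaled_count: float,
                          historical_count: float,
                          area_factor: float = 8.0) -> float:
    """Contemporary catch as a percentage of a historical benchmark.

    ``mean_scaled_count`` must already include the x``area_factor`` trap-
    area rescaling (a 2 m^2 trap against a historical 16 m^2 one).
    """
    if historical_count <= 0:
        raise ValueError("historical count must be positive")
    if area_factor <= 0:
        raise ValueError("area factor must be positive")
    return 100.0 * mean_scaled_count / historical_count
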