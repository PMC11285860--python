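"""Synthetic field seasons with the statistical structure the pipeline assumes.

The generator emulates an autumn monitoring campaign at a mountain-pass
migration bottleneck: daily weather covariates, zero-inflated
negative-binomial daily migration totals driven by those covariates,
multinomial within-day allocation to 15-min video bins peaking ~1 h after
solar noon, bidirectional trap catches with wind-conditional southward bias
per taxon, sun-present/absent fine-scale count contrasts and binomial sex
ratios.  Every stage draws from a sub-stream derived deterministically from
the master seed, so each stage is individually reproducible.

The tables written by :func:`simulate_season` use exactly the delimited
schemas that :mod:`passflow.io` reads, so synthetic seasons are drop-in
replacements for field data.
"""

from __future__ import annotations

import zlib
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .config import SimConfig, ZINBParams, TaxonProfile
from .io import assign_wind_category
from . import weather as wm

__all__ = [
    "stage_rng", "simulate_weather", "simulate_daily_totals",
    "allocate_within_day", "simulate_trap_catch", "simulate_sun_occasions",
    "simulate_sexed_individuals", "simulate_season",
]

#: 15-min video bins per observation day (09:00-17:00)
N_BINS = 32
BIN_MINUTES = 15
DAY_START_HOUR = 9


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one master seed."""
    tag = zlib.crc32(stage.encode("utf8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([master_seed, tag]))


def _season_dates(config: SimConfig) -> pd.DatetimeIndex:
    # spread n_days evenly over the configured seasons' Sep-Oct windows
    seasons = list(config.seasons) or [2021]
    base = config.n_days // len(seasons)
    extra = config.n_days - base * len(seasons)
    dates = []
    for i, year in enumerate(seasons):
        k = base + (1 if i < extra else 0)
        start = datetime(int(year), 9, 1)
        dates.extend(start + timedelta(days=d) for d in range(k))
    return pd.DatetimeIndex(dates[:config.n_days])


def simulate_weather(config: SimConfig, seed: int = None) -> pd.DataFrame:
    """Draw a daily weather table with derived ``h`` and ``s`` columns.

    Marginals span the autumn conditions at a ~2300 m pass: truncated-normal
    temperature, zero-heavy gamma rainfall, uniform wind heading, gamma
    windspeed and beta-distributed sunshine over the 480-min observation
    window.  Covariates are independent across days and variables.
    """
    if config.n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = stage_rng(config.rng_seed if seed is None else seed, "weather")
    n = config.n_days
    lo, hi = config.temp_range_c
    temp = np.clip(rng.normal(config.temp_mean_c, config.temp_sd_c, n), lo, hi)
    rainy = rng.random(n) < config.p_rainy
    rain = np.where(
        rainy,
        rng.gamma(config.rain_shape,
                  config.rain_mean_mm / config.rain_shape, n),
        0.0)
    heading = rng.uniform(0.0, 360.0, n)
    windspeed = rng.gamma(2.0, config.windspeed_mean_ms / 2.0, n)
    a, b = config.sunshine_beta
    sunshine = rng.beta(a, b, n) * 480.0
    df = pd.DataFrame({
        "date": _season_dates(config),
        "temp_c": temp,
        "wind_heading_deg": heading,
        "rain_mm": rain,
        "windspeed_ms": windspeed,
        "sunshine_min": sunshine,
    })
    return wm.derive_covariates(df)


def simulate_daily_totals(weather: pd.DataFrame, params: ZINBParams,
                          seed: int = 0) -> pd.DataFrame:
    """Draw integrated daily migration totals from the ZINB model.

    With probability ``pi = cauchit(z'gamma)`` a day is a structural zero;
    otherwise the total is NB with mean ``exp(x'beta)`` and dispersion
    ``theta``.
    """
    for col in ("h", "s"):
        if col not in weather.columns:
            raise ValueError(
                f"weather table lacks derived covariate {col!r}; "
                "run derive_covariates first")
    rng = stage_rng(seed, "daily-totals")
    X, _ = wm.build_design(weather, [t for t in params.beta
                                     if t != "intercept"])
    Z, _ = wm.build_design(weather, [t for t in params.gamma
                                     if t != "intercept"])
    beta = np.array([params.beta["intercept"]]
                    + [v for k, v in params.beta.items() if k != "intercept"])
    gamma = np.array([params.gamma["intercept"]]
                     + [v for k, v in params.gamma.items() if k != "intercept"])
    # cap the linear predictor: keeps NB sampling inside int64/Poisson range
    mu = np.exp(np.clip(X @ beta, -500, 30))
    pi = wm.cauchit(Z @ gamma)
    structural = rng.random(len(weather)) < pi
    p_nb = params.theta / (params.theta + mu)
    counts = rng.negative_binomial(params.theta, p_nb)
    counts[structural] = 0
    return pd.DataFrame({"date": weather["date"].values,
                         "total_count": counts.astype(np.int64)})


def _bin_weights(config: SimConfig) -> np.ndarray:
    # discretized triangular kernel (default half-width 2 h) over a uniform
    # background: low-level movement all day, a pronounced afternoon peak.
    # the background share keeps the off-peak bins occupied while the
    # triangle gives the peak bin a clear contrast over its neighbours
    peak_bin = int(config.diurnal_peak_minutes_after_0900 // BIN_MINUTES)
    peak_bin = min(max(peak_bin, 0), N_BINS - 1)
    idx = np.arange(N_BINS, dtype=float)
    tri = np.clip(1.0 - np.abs(idx - peak_bin) / config.diurnal_halfwidth_bins,
                  0.0, None)
    tri /= tri.sum()
    bg = config.diurnal_background
    w = bg / N_BINS + (1.0 - bg) * tri
    return w / w.sum()


def allocate_within_day(total: int, config: SimConfig,
                        seed: int = 0) -> pd.DataFrame:
    """Split a daily total over the 32 15-min bins (09:00-17:00).

    Multinomial allocation with a unimodal (triangular) weight profile whose
    mode is the configured peak bin; bin counts sum exactly to ``total``.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    rng = stage_rng(seed, "within-day")
    counts = rng.multinomial(int(total), _bin_weights(config))
    minutes = DAY_START_HOUR * 60 + np.arange(N_BINS) * BIN_MINUTES
    return pd.DataFrame({
        "bin_start": [f"{m // 60:02d}:{m % 60:02d}" for m in minutes],
        "count": counts.astype(np.int64),
    })


def simulate_trap_catch(profiles, weather: pd.DataFrame,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate bidirectional trap records with wind-conditional bias.

    Per taxon and day the total catch is Poisson with the profile's mean
    (scaled by ``tailwind_abundance_factor`` on tailwind days) and is split
    south/north binomially with the wind-matched southward probability.
    """
    rng = stage_rng(seed, "trap")
    wind = assign_wind_category(np.asarray(weather["h"], dtype=float))
    dates = weather["date"].values
    rows = []
    for prof in profiles:
        if not isinstance(prof, TaxonProfile):
            prof = TaxonProfile(**prof)
        for d, wc in zip(dates, wind):
            mean = prof.daily_abundance_mean
            p_south = prof.p_south_headwind
            if wc == "tailwind":
                mean *= prof.tailwind_abundance_factor
                p_south = prof.p_south_tailwind
            if mean <= 0:
                continue
            n = int(rng.poisson(mean))
            if n == 0:
                continue
            n_south = int(rng.binomial(n, p_south))
            for direction, cnt in (("south", n_south), ("north", n - n_south)):
                if cnt > 0:
                    rows.append((d, prof.taxon, direction, cnt, wc))
    return pd.DataFrame(rows, columns=["date", "taxon", "direction", "count",
                                       "wind_category"])


def simulate_sun_occasions(n_occasions: int, sun_fold: float, seed: int = 0,
                           shade_mean: float = 2.0, theta: float = 1.5,
                           p_sun: float = 0.5) -> pd.DataFrame:
    """Simulate fine-scale counting occasions under sun vs shade.

    Sunny occasions draw NB counts with mean ``sun_fold`` times the shaded
    mean (same dispersion).  The split between classes is fixed at
    ``round(p_sun * n)`` (both classes always non-empty) and the labels
    shuffled, so relabelling has no effect on the class statistics.
    """
    if n_occasions < 2:
        raise ValueError("need at least 2 occasions")
    if sun_fold <= 0:
        raise ValueError("sun_fold must be positive")
    rng = stage_rng(seed, "sun-occasions")
    n_sun = int(np.clip(round(p_sun * n_occasions), 1, n_occasions - 1))
    sun = np.zeros(n_occasions, dtype=bool)
    sun[:n_sun] = True
    rng.shuffle(sun)
    mean = np.where(sun, sun_fold * shade_mean, shade_mean)
    counts = rng.negative_binomial(theta, theta / (theta + mean))
    return pd.DataFrame({"occasion": np.arange(n_occasions),
                         "sun_present": sun,
                         "count": counts.astype(np.int64)})


def simulate_sexed_individuals(config: SimConfig, seed: int = 0) -> pd.DataFrame:
    """Binomial female counts per taxon at the configured ratios."""
    rng = stage_rng(seed, "sex-ratios")
    rows = []
    for taxon, frac in config.sex_ratios.items():
        n = int(config.sex_sample_sizes.get(taxon, 500))
        females = int(rng.binomial(n, frac))
        rows.append((taxon, n, females, n - females))
    return pd.DataFrame(rows, columns=["taxon", "n", "n_female", "n_male"])


def simulate_season(config: SimConfig, missed_fraction: float = 0.57):
    """Generate one complete synthetic campaign.

    Returns a dict of tables: ``weather``, ``daily_totals`` (integrated
    pass-level totals), ``video`` (raw 1-min counts per 15-min bin, i.e. the
    resolvable fraction of the total back-scaled through the x225 video
    scaling), ``visual`` (bi-hourly butterfly counts), ``trap`` and
    ``sexed``.
    """
    seed = config.rng_seed
    weather = simulate_weather(config)
    totals = simulate_daily_totals(weather, config.zinb_params, seed)
    video_scale = 225.0  # x15 time, x15 width: raw -> pass-level
    rows = []
    visual_rows = []
    rng_vis = stage_rng(seed, "visual")
    for i, (date, total) in enumerate(
            zip(totals["date"], totals["total_count"])):
        # integrated total -> raw video counts: remove butterfly share,
        # keep the resolvable fraction, undo the x225 scaling
        video_part = total * (1.0 - config.butterfly_share)
        raw_day = int(round(video_part * (1.0 - missed_fraction)
                            / video_scale))
        bins = allocate_within_day(raw_day, config, seed=seed + i + 1)
        ts = pd.Timestamp(date)
        for bin_start, cnt in zip(bins["bin_start"], bins["count"]):
            h, m = map(int, bin_start.split(":"))
            rows.append((ts + pd.Timedelta(hours=h, minutes=m),
                         1.0, 2.0, int(cnt)))
        # four 15-min visual counts (10:00-16:00 every 2 h), x8 scaling
        butt_day = total * config.butterfly_share
        raw_visual = rng_vis.multinomial(int(round(butt_day / 8.0)),
                                         np.full(4, 0.25))
        for j, cnt in enumerate(raw_visual):
            visual_rows.append((ts + pd.Timedelta(hours=10 + 2 * j),
                                15.0, 30.0, "Pieridae", int(cnt),
                                float(rng_vis.uniform(0, 100))))
    video = pd.DataFrame(rows, columns=["timestamp", "duration_min",
                                        "width_m", "count"])
    visual = pd.DataFrame(visual_rows,
                          columns=["timestamp", "duration_min", "width_m",
                                   "taxon", "count", "sun_percent"])
    trap = simulate_trap_catch(config.taxon_profiles, weather, seed)
    sexed = simulate_sexed_individuals(config, seed)
    return {"weather": weather, "daily_totals": totals, "video": video,
            "visual": visual, "trap": trap, "sexed": sexed}
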