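"""Fine-temporal-scale effects of direct sunlight on migration counts.

Two complementary analyses:

* :func:`sun_presence_test` — 15-min video counting occasions labelled
  sun-present/sun-absent.  Reports the fold difference of raw class means
  and a two-sample t statistic on transformed counts (default Welch on
  log1p, both configurable).  The test is oriented (shade - sun), so a
  positive sun effect yields a negative t.
* :func:`sun_linear_fit` — bi-hourly visual counts against percent
  sunshine (0-100) by ordinary least squares, reporting slope, R² and the
  F test with (1, n-2) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = ["SunComparison", "LinearSunFit", "sun_presence_test",
           "sun_linear_fit"]


@dataclass
class SunComparison:
    n_sun: int
    n_shade: int
    mean_sun: float
    mean_shade: float
    fold: float  # mean_sun / mean_shade; NaN when the shade mean is zero
    t_stat: float
    df: float
    p_value: float


@dataclass
class LinearSunFit:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


_TRANSFORMS = {"log1p": np.log1p, "identity": lambda x: x, None: lambda x: x}


def sun_presence_test(occasions: pd.DataFrame, transform: str = "log1p",
                      equal_var: bool = False) -> SunComparison:
    """Compare counts between sun-present and sun-absent occasions.

    ``occasions`` needs boolean ``sun_present`` and integer ``count``
    columns.  The fold is the ratio of raw means (NaN-flagged when the
    shade mean is zero); the t statistic is computed shade-minus-sun on the
    transformed counts (Welch by default).
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    f = _TRANSFORMS[transform]
    sun = occasions.loc[occasions["sun_present"].astype(bool), "count"]
    shade = occasions.loc[~occasions["sun_present"].astype(bool), "count"]
    if len(sun) == 0 or len(shade) == 0:
        raise ValueError("both sun and shade classes must be non-empty")
    mean_sun = float(sun.mean())
    mean_shade = float(shade.mean())
    fold = mean_sun / mean_shade if mean_shade > 0 else float("nan")
    res = stats.ttest_ind(f(shade.to_numpy(dtype=float)),
                          f(sun.to_numpy(dtype=float)),
                          equal_var=equal_var)
    return SunComparison(
        n_sun=len(sun), n_shade=len(shade),
        mean_sun=mean_sun, mean_shade=mean_shade, fold=fold,
        t_stat=float(res.statistic), df=float(res.df),
        p_value=float(res.pvalue))


def sun_linear_fit(visual: pd.DataFrame) -> LinearSunFit:
    """OLS of visual counts on percent sunshine (0-100)."""
    df = visual[["sun_percent", "count"]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 observations")
    x = df["sun_percent"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("sun_percent is constant; slope unidentifiable")
    y = df["count"].to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearSunFit(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r_squared=float(model.rsquared), f_stat=float(model.fvalue),
        df_num=int(model.df_model), df_den=int(model.df_resid),
        p_value=float(model.f_pvalue))
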