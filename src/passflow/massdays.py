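"""Mass-migration day selection and the mean diurnal activity profile.

Mass-migration days are found by ranking all observation days by their
integrated insect total (descending) and taking the shortest prefix whose
cumulative sum reaches the configured share (default 95%) of the grand
total; the crossing day is included.  Ties in the total are broken by
earlier date so the selection is deterministic.

The diurnal profile averages each 15-min video bin (09:00-17:00, 32 bins)
over the selected days; its argmax (earliest bin on ties) is the daily
activity peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MassMigrationResult", "select_mass_days", "diurnal_profile"]


@dataclass
class MassMigrationResult:
    ranked_days: pd.DataFrame      # date, total; descending by total
    selected_days: pd.DataFrame    # the chosen prefix
    cumulative_fraction_at_cut: float
    n_selected: int


def select_mass_days(daily_totals: pd.DataFrame,
                     fraction: float = 0.95) -> MassMigrationResult:
    """Smallest descending-sorted prefix of days reaching the target share.

    ``daily_totals`` needs ``date`` and ``total_count`` columns; days with
    zero counts can never be selected.  Raises if nothing was recorded.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    df = daily_totals[["date", "total_count"]].copy()
    df["date"] = pd.to_datetime(df["date"])
    grand = float(df["total_count"].sum())
    if grand <= 0:
        raise ValueError("no migration observed: all daily totals are zero")
    ranked = df.sort_values(["total_count", "date"],
                            ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
    cum = ranked["total_count"].cumsum() / grand
    # first index where the cumulative share reaches the target
    n_sel = int(np.searchsorted(cum.to_numpy(), fraction - 1e-12) + 1)
    n_sel = min(n_sel, int((ranked["total_count"] > 0).sum()))
    selected = ranked.iloc[:n_sel].copy()
    return MassMigrationResult(
        ranked_days=ranked, selected_days=selected,
        cumulative_fraction_at_cut=float(cum.iloc[n_sel - 1]),
        n_selected=n_sel)


def diurnal_profile(video: pd.DataFrame, selected_days) -> dict:
    """Mean 15-min profile over the selected days, plus the peak bin.

    ``video`` holds raw per-bin counts with bin-start timestamps; selected
    days without any video coverage are dropped (listed under
    ``days_without_video``).  Returns the per-bin mean profile indexed by
    clock time, the peak bin label and the number of days averaged.
    """
    sel = pd.DatetimeIndex(pd.to_datetime(list(selected_days))).normalize()
    if len(sel) == 0:
        raise ValueError("no selected days")
    vid = video.copy()
    vid["day"] = pd.to_datetime(vid["timestamp"]).dt.normalize()
    vid["bin"] = pd.to_datetime(vid["timestamp"]).dt.strftime("%H:%M")
    covered = sel.intersection(pd.DatetimeIndex(vid["day"].unique()))
    dropped = sel.difference(covered)
    if len(covered) == 0:
        raise ValueError("none of the selected days has video coverage")
    sub = vid[vid["day"].isin(covered)]
    profile = (sub.groupby("bin")["count"].mean().sort_index())
    peak = profile.index[int(np.argmax(profile.to_numpy()))]
    return {"profile": profile, "peak_bin": peak,
            "n_days": len(covered),
            "days_without_video": [str(d.date()) for d in dropped]}
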