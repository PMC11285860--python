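"""Wind-conditional southward scores and migrant classification.

A taxon's *southward score* in a wind category is the percentage of trapped
individuals heading south minus the percentage heading north, i.e.
``100 * (n_south - n_north) / n_total`` in [-100, 100].  Scores are only
defined once at least ``min_group_n`` individuals (default 100) were caught
in that wind category.

Categories, applied in order:

* **HighAltitude** — headwind score >= 90 and fewer than 100 individuals in
  tailwinds: the taxon fights headwinds through the pass but overflies the
  ridge when winds assist.
* **FBL** (flight-boundary-layer) — defined scores in both wind categories
  with tailwind score >= 50: directed low-altitude movement regardless of
  wind.
* **NonMigratory** — enough individuals overall (>= 100) but matching
  neither rule.
* **Unclassified** — too few individuals to analyse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import assign_wind_category

__all__ = ["SouthwardScore", "MigrantClass", "southward_score",
           "score_from_records", "classify_taxon", "classify_assemblage"]


@dataclass(frozen=True)
class SouthwardScore:
    taxon: str
    wind_category: str
    n_south: int
    n_north: int
    score: float  # None when n_total < min_group_n

    @property
    def n_total(self) -> int:
        return self.n_south + self.n_north

    @property
    def defined(self) -> bool:
        return self.score is not None


@dataclass(frozen=True)
class MigrantClass:
    taxon: str
    category: str  # HighAltitude | FBL | NonMigratory | Unclassified
    head: SouthwardScore
    tail: SouthwardScore


def southward_score(n_south: int, n_north: int, taxon: str = "",
                    wind_category: str = "", min_group_n: int = 100
                    ) -> SouthwardScore:
    """Score = %south - %north; undefined below the sample-size floor."""
    if n_south < 0 or n_north < 0:
        raise ValueError("counts must be non-negative")
    n = n_south + n_north
    score = 100.0 * (n_south - n_north) / n if n >= min_group_n else None
    return SouthwardScore(taxon, wind_category, int(n_south), int(n_north),
                          score)


def score_from_records(records: pd.DataFrame, taxon: str, wind_category: str,
                       min_group_n: int = 100) -> SouthwardScore:
    """Aggregate trap records of one taxon and wind category into a score."""
    sub = records[(records["taxon"] == taxon)
                  & (records["wind_category"] == wind_category)]
    n_south = int(sub.loc[sub["direction"] == "south", "count"].sum())
    n_north = int(sub.loc[sub["direction"] == "north", "count"].sum())
    return southward_score(n_south, n_north, taxon, wind_category,
                           min_group_n)


def classify_taxon(head: SouthwardScore, tail: SouthwardScore,
                   config: PipelineConfig = None) -> MigrantClass:
    """Apply the category rules to one taxon's head/tail scores."""
    config = config or PipelineConfig()
    taxon = head.taxon or tail.taxon
    if (head.defined and head.score >= config.high_altitude_score_min
            and tail.n_total < config.min_group_n):
        cat = "HighAltitude"
    elif (head.defined and tail.defined
          and tail.score >= config.fbl_tailwind_score_min):
        cat = "FBL"
    elif head.n_total + tail.n_total >= config.min_group_n:
        cat = "NonMigratory"
    else:
        cat = "Unclassified"
    return MigrantClass(taxon, cat, head, tail)


def classify_assemblage(trap: pd.DataFrame, weather: pd.DataFrame,
                        config: PipelineConfig = None) -> dict:
    """Classify every trapped taxon and summarize assemblage composition.

    Wind categories are taken from the trap records when present, else
    joined from the weather table's headwind index.  Returns a dict with a
    per-taxon ``classes`` table and composition percentages of migratory
    individuals (HighAltitude + FBL) by order.
    """
    config = config or PipelineConfig()
    trap = trap.copy()
    if "wind_category" not in trap.columns or trap["wind_category"].isna().any():
        wx = weather.copy()
        wx["wind_category"] = assign_wind_category(
            np.asarray(wx["h"], dtype=float), config.wind_deadband)
        missing = set(pd.to_datetime(trap["date"]).dt.normalize()) - set(
            pd.to_datetime(wx["date"]).dt.normalize())
        if missing:
            raise ValueError(
                "trap dates missing from weather table: "
                + ", ".join(sorted(str(d.date()) for d in missing)))
        trap = trap.drop(columns=["wind_category"], errors="ignore").merge(
            wx[["date", "wind_category"]], on="date", how="left")

    rows = []
    classes = {}
    for taxon in sorted(trap["taxon"].unique()):
        head = score_from_records(trap, taxon, "headwind", config.min_group_n)
        tail = score_from_records(trap, taxon, "tailwind", config.min_group_n)
        mc = classify_taxon(head, tail, config)
        classes[taxon] = mc
        rows.append({
            "taxon": taxon, "category": mc.category,
            "head_n": head.n_total, "head_score": head.score,
            "tail_n": tail.n_total, "tail_score": tail.score,
        })
    table = pd.DataFrame(rows)

    migratory = table[table["category"].isin(["HighAltitude", "FBL"])]
    counts = (trap.groupby("taxon")["count"].sum()
              .reindex(migratory["taxon"]).fillna(0))
    total = counts.sum()
    if total > 0 and config.taxon_orders:
        orders = counts.groupby(
            counts.index.map(lambda t: config.taxon_orders.get(t, "Unknown"))
        ).sum()
        order_pct = (100.0 * orders / total).sort_values(ascending=False)
    else:
        order_pct = pd.Series(dtype=float)
    family_pct = (100.0 * counts / total).sort_values(ascending=False) \
        if total > 0 else pd.Series(dtype=float)
    return {"classes": table, "order_percent": order_pct,
            "family_percent": family_pct}
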