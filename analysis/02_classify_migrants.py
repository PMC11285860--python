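#!/usr/bin/env python
"""Classify trapped taxa into migrant categories from directional catches.

Reads the simulated trap and weather tables, computes wind-conditional
southward scores and applies the high-altitude / flight-boundary-layer
rules; writes the classification table and prints the migratory
composition.
"""

from pathlib import Path

from passflow import io as pio
from passflow.classify import classify_assemblage
from passflow.config import PipelineConfig, SimConfig

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    trap = pio.read_table(ROOT / "season" / "trap.tsv", "trap")
    weather = pio.read_table(ROOT / "season" / "weather.tsv", "weather")
    sim = SimConfig()
    pipe = PipelineConfig(
        taxon_orders={p.taxon: p.order for p in sim.taxon_profiles})
    res = classify_assemblage(trap, weather, pipe)
    res["classes"].to_csv(ROOT / "classification.tsv", sep="\t", index=False)
    print(res["classes"].to_string(index=False))
    n_mig = (res["classes"]["category"]
             .isin(["HighAltitude", "FBL"]).sum())
    print(f"\n{n_mig} of {len(res['classes'])} taxa show migratory "
          "behaviour; composition of migratory individuals by order (%):")
    print(res["order_percent"].round(1).to_string())


if __name__ == "__main__":
    main()
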