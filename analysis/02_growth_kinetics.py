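#!/usr/bin/env python
"""Estimate HNF growth parameters for every simulated treatment.

Reads results/simulation/abundance_all.tsv (run 01 first), fits the pooled
lag/exponential/plateau model per treatment, and reports doubling time, lag
phase, gross growth efficiency and relative growth rate — the quantities a
prey-quality comparison turns on.  Writes results/growth_params.tsv.
"""

from pathlib import Path

from bacterivory import io
from bacterivory.growth import summarize_growth

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    series = io.read_abundance_tsv(ROOT / "simulation" / "abundance_all.tsv")
    table = summarize_growth(series)
    io.write_tsv(table, ROOT / "growth_params.tsv")
    means = table[table.statistic == "mean"].set_index("treatment")
    print("treatment  DT(h)  lag(h)  GGE    rel.growth(%)")
    for t, r in means.iterrows():
        print(f"{t:<9}  {r.doubling_time:5.1f}  {r.lag:5.1f}  {r.gge:.2f}   "
              f"{r.relative_growth:5.0f}")
    fastest = means.doubling_time.idxmin()
    print(f"\nfastest growth on {fastest} "
          f"(DT {means.loc[fastest].doubling_time:.1f} h); "
          f"growth parameters written to {ROOT / 'growth_params.tsv'}")


if __name__ == "__main__":
    main()
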