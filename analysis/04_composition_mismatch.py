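#!/usr/bin/env python
"""Compare amplicon-read vs CARD-FISH composition and estimate copy bias.

Uses the published t0 compositions (reads: 44 % Katablepharidophyta, 47 %
Cryptophyta; FISH: 1.5 % and 62.5 % of DAPI-stained HNF) to quantify the
read/cell mismatch, then shows on simulated data that the implied rRNA
copy-number ratio is recoverable from paired read and FISH fractions.
Writes results/composition_bias.tsv.
"""

from pathlib import Path

import pandas as pd

from bacterivory import io
from bacterivory.composition import bias_table, estimate_copy_bias
from bacterivory.validation import copy_bias_recovery

ROOT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    reads = {"Katablepharidophyta": 0.44, "Cryptophyta": 0.47}
    fish = {"Katablepharidophyta": 0.015, "Cryptophyta": 0.625}
    bias = bias_table(reads, fish)
    factors = estimate_copy_bias(reads, fish)
    bias["copy_factor_geo_mean_1"] = bias.group.map(factors)
    io.write_tsv(bias, ROOT / "composition_bias.tsv")
    print(bias.to_string(index=False))
    kata = bias.set_index("group").loc["Katablepharidophyta"]
    print(f"\nKatablepharidophyta are 2^{kata.log2_ratio:.1f} = "
          f"{2**kata.log2_ratio:.0f}x overrepresented in reads relative to "
          f"cells; Cryptophyta are underrepresented.")

    rec = copy_bias_recovery(seed=seed)
    print(f"simulated check: a {rec['true_ratio']:.0f}:1 copy-number ratio is "
          f"recovered as {rec['estimated_ratio']:.1f}:1 from reads at depth "
          f"1e5 and 1e3 inspected cells.")


if __name__ == "__main__":
    main()
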