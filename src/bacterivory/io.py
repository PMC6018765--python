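"""TSV readers/writers for the tabular schemas used across the package.

All tables are UTF-8, tab-separated, dot decimal, one header row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .growth import AbundanceSeries

ABUNDANCE_COLUMNS = [
    "treatment", "replicate", "time_h", "bacteria_per_ml", "hnf_per_ml",
    "bact_mcv_um3", "hnf_mcv_um3",
]


def read_abundance_tsv(path: str | Path) -> dict[str, list[AbundanceSeries]]:
    """Load an abundance time-series table into per-treatment replicate lists."""
    return abundance_frame_to_series(pd.read_csv(path, sep="\t"))


def abundance_frame_to_series(df: pd.DataFrame) -> dict[str, list[AbundanceSeries]]:
    """Group a long-form abundance table into AbundanceSeries per treatment."""
    missing = set(ABUNDANCE_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"abundance table missing columns: {sorted(missing)}")
    out: dict[str, list[AbundanceSeries]] = {}
    for (treatment, replicate), g in df.groupby(["treatment", "replicate"], sort=False):
        g = g.sort_values("time_h")
        out.setdefault(str(treatment), []).append(
            AbundanceSeries(
                treatment=str(treatment),
                replicate=int(replicate),
                times=g["time_h"].to_numpy(),
                bacteria=g["bacteria_per_ml"].to_numpy(),
                hnf=g["hnf_per_ml"].to_numpy(),
                bact_mcv=g["bact_mcv_um3"].to_numpy() if "bact_mcv_um3" in g else None,
                hnf_mcv=g["hnf_mcv_um3"].to_numpy() if "hnf_mcv_um3" in g else None,
            )
        )
    return out


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_manifest(params, path: str | Path) -> None:
    """Record generator ground truth as flat key-value lines."""
    lines = []
    for key, val in vars(params).items():
        if isinstance(val, dict):
            for k, v in val.items():
                lines.append(f"{key}.{k}\t{v}")
        else:
            lines.append(f"{key}\t{val}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_reads_tsv(path: str | Path) -> pd.DataFrame:
    """Group x sample read-count matrix in long or wide form -> long form."""
    df = pd.read_csv(path, sep="\t")
    if {"group", "reads"} <= set(df.columns):
        return df
    long = df.melt(id_vars=[df.columns[0]], var_name="sample", value_name="reads")
    return long.rename(columns={df.columns[0]: "group"})


def read_fish_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"probe", "hybridized", "n_inspected"}
    if not needed <= set(df.columns):
        raise ValueError(f"FISH table needs columns {sorted(needed)}")
    return df
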