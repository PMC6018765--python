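"""Amplicon-read vs CARD-FISH composition comparison and rRNA copy-number bias.

Relative abundances of protist groups estimated from 18S amplicon reads can
disagree sharply with cell proportions counted by CARD-FISH on the same
samples, because read share is proportional to cell share times the
per-group rRNA gene copy number (and further modulated by primer and probe
efficiencies).  This module computes both composition estimates on a common
group set, the per-group log2 read/cell ratio ("bias table"), and a
copy-number factor estimate identifiable up to a multiplicative constant
(reported with geometric mean 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompositionSample",
    "read_fractions",
    "fish_fractions",
    "bias_table",
    "estimate_copy_bias",
]


@dataclass
class CompositionSample:
    """Per-sample group read counts plus per-probe FISH counts."""

    sample_id: str
    read_counts: dict[str, int]
    fish_hybridized: dict[str, int]
    n_inspected: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, c in self.read_counts.items():
            if c < 0 or not math.isfinite(c):
                raise ValueError(f"read count for {g} must be a finite non-negative number")
        for p, h in self.fish_hybridized.items():
            n = self.n_inspected.get(p, h)
            if h < 0 or h > n:
                raise ValueError(f"hybridized count for {p} must lie in [0, n_inspected]")


def read_fractions(
    read_counts: dict[str, float],
    include_groups: list[str] | None = None,
    pseudo: float = 0.0,
) -> dict[str, float]:
    """Read counts restricted to ``include_groups`` and renormalised to sum 1.

    ``pseudo`` reads are added to every included group before normalising
    (useful ahead of log-ratio work; default 0 leaves counts untouched).
    """
    if include_groups is None:
        include_groups = list(read_counts)
    if not include_groups:
        raise ValueError("include_groups must be non-empty")
    counts = np.array([read_counts.get(g, 0) + pseudo for g in include_groups], dtype=float)
    if np.any(counts < 0):
        raise ValueError("read counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("no reads in the included groups")
    return dict(zip(include_groups, counts / total))


def fish_fractions(
    hybridized: dict[str, int] | int,
    n_inspected: dict[str, int] | int,
) -> pd.DataFrame:
    """Hybridised cell fraction per probe with its binomial standard error.

    Accepts either scalars (one probe) or dicts keyed by probe.  The
    fraction is hybridized/n_inspected relative to DAPI-stained cells;
    s.e. = sqrt(p(1-p)/n).
    """
    if not isinstance(hybridized, dict):
        hybridized = {"probe": hybridized}
        n_inspected = {"probe": n_inspected}
    rows = []
    for probe, h in hybridized.items():
        n = n_inspected[probe] if isinstance(n_inspected, dict) else n_inspected
        if n <= 0:
            raise ValueError(f"n_inspected must be positive for probe {probe}")
        if h < 0 or h > n:
            raise ValueError(f"hybridized count out of [0, n] for probe {probe}")
        p = h / n
        rows.append(
            {"probe": probe, "fraction": p, "se": math.sqrt(p * (1 - p) / n), "n": n}
        )
    return pd.DataFrame(rows)


def bias_table(
    read_frac: dict[str, float],
    fish_frac: dict[str, float],
    pseudo: float = 0.5,
    total_reads: float | None = None,
) -> pd.DataFrame:
    """Per-group log2(read fraction / FISH fraction); positive means the
    group is overrepresented in reads.

    Zero fractions would give infinite log-ratios; when ``total_reads`` is
    supplied, a zero entry on either side is floored at ``pseudo`` pseudo-
    counts out of that total (the FISH side uses the same floor as a
    detection limit).  Groups present in neither input are skipped with a
    warning.
    """
    shared = [g for g in read_frac if g in fish_frac]
    dropped = set(read_frac) ^ set(fish_frac)
    if dropped:
        warnings.warn(f"groups absent from one input skipped: {sorted(dropped)}")
    if not shared:
        raise ValueError("no shared groups between read and FISH inputs")
    floor = pseudo / total_reads if total_reads else 0.0
    rows = []
    for g in shared:
        r = max(read_frac[g], floor)
        f = max(fish_frac[g], floor)
        if r <= 0 or f <= 0:
            warnings.warn(f"group {g} has a zero fraction and no floor; skipped")
            continue
        rows.append({"group": g, "read_frac": read_frac[g], "fish_frac": fish_frac[g],
                     "log2_ratio": math.log2(r / f)})
    return pd.DataFrame(rows)


def estimate_copy_bias(
    read_frac: dict[str, float],
    fish_frac: dict[str, float],
) -> dict[str, float]:
    """Relative rRNA copy-number factors, normalised to geometric mean 1.

    Under multinomial read sampling with per-group copy factors c_g, the
    expected read fraction is proportional to cell_fraction * c_g, so
    c_g is estimated as read_frac/fish_frac up to a constant.  Only the
    *ratios* between groups are identifiable; equal FISH probe efficiencies
    across groups are assumed (a group-specific efficiency is absorbed into
    its factor).  Groups with a zero FISH fraction are excluded with a
    warning.
    """
    shared = [g for g in read_frac if g in fish_frac]
    if not shared:
        raise ValueError("no shared groups")
    usable, ratios = [], []
    for g in shared:
        if fish_frac[g] <= 0:
            warnings.warn(f"group {g} has zero FISH fraction; excluded from copy-bias fit")
            continue
        if read_frac[g] <= 0:
            warnings.warn(f"group {g} has zero read fraction; excluded from copy-bias fit")
            continue
        usable.append(g)
        ratios.append(read_frac[g] / fish_frac[g])
    if not usable:
        raise ValueError("no group with positive fractions on both sides")
    log_ratios = np.log(ratios)
    log_ratios -= log_ratios.mean()  # geometric mean 1
    return dict(zip(usable, np.exp(log_ratios)))
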