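"""Cell and community biovolume calculus for microscopy-based plankton counts.

Heterotrophic nanoflagellates (HNFs) and their bacterial prey are sized from
epifluorescence length/width measurements by approximating each cell as a
prolate spheroid, V = (pi/6) * L * W**2.  Community biovolume (um^3 ml^-1) is
abundance times mean cell volume.  Prey-amendment experiments equalise the
*biovolume* added across strains of very different cell size, so per-strain
cell concentrations are derived from a common added biovolume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StrainSpec",
    "prolate_spheroid_volume",
    "mean_cell_volume",
    "community_biovolume",
    "prey_addition_concentrations",
    "load_strain_table",
]


@dataclass(frozen=True)
class StrainSpec:
    """Morphometry of one prey bacterial strain.

    volume is the mean cell volume in um^3, length the major axis in um.
    The implied mean width must not exceed the length: volume <= (pi/6) L^3.
    """

    strain_id: str
    lineage: str
    volume: float
    length: float
    shape: str = ""

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.length <= 0:
            raise ValueError("strain volume and length must be positive")
        if self.volume > (math.pi / 6) * self.length**3 * (1 + 1e-9):
            raise ValueError(
                f"strain {self.strain_id}: volume {self.volume} exceeds the "
                f"sphere bound (pi/6) L^3 for length {self.length}"
            )

    @property
    def width(self) -> float:
        """Mean width implied by volume and length, W = sqrt(6V / (pi L))."""
        return math.sqrt(6 * self.volume / (math.pi * self.length))


def prolate_spheroid_volume(length: float, width: float) -> float:
    """Volume of a prolate spheroid, V = (pi/6) * L * W^2 (um^3).

    ``length`` must be the major axis; callers with unordered microscopy
    columns should orient them first (see :func:`mean_cell_volume`).
    """
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(width <= 0) or np.any(length <= 0):
        raise ValueError("length and width must be positive")
    if np.any(width > length * (1 + 1e-12)):
        raise ValueError("width exceeds length; orient axes before calling")
    out = (math.pi / 6.0) * length * width**2
    return float(out) if out.ndim == 0 else out


def mean_cell_volume(
    measurements: Iterable[tuple[float, float]] | pd.DataFrame,
    *,
    orient: bool = True,
) -> float:
    """Arithmetic mean of per-cell prolate-spheroid volumes.

    ``measurements`` is an iterable of (length, width) pairs or a DataFrame
    with ``length_um``/``width_um`` columns.  With ``orient=True`` (default)
    each pair is sorted so the larger dimension is treated as the length;
    microscopy tables do not guarantee axis order.
    """
    if isinstance(measurements, pd.DataFrame):
        arr = measurements[["length_um", "width_um"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(measurements), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one cell measurement is required")
    arr = arr.reshape(-1, 2)
    if orient:
        arr = np.sort(arr, axis=1)[:, ::-1]
    vols = prolate_spheroid_volume(arr[:, 0], arr[:, 1])
    return float(np.mean(vols))


def community_biovolume(abundance: float, mcv: float) -> float:
    """Population biovolume (um^3 ml^-1) = abundance (cells ml^-1) x mean cell volume."""
    if abundance < 0 or mcv < 0:
        raise ValueError("abundance and mean cell volume must be non-negative")
    return float(abundance) * float(mcv)


def prey_addition_concentrations(
    strains: Sequence[StrainSpec],
    background_conc: float,
    background_mcv: float,
    factor: float = 10.0,
) -> pd.DataFrame:
    """Per-strain cell concentrations for biovolume-equalised prey additions.

    Every strain is added at the same biovolume, ``factor`` times the ambient
    bacterial biovolume (background_conc x background_mcv); small-celled
    strains therefore go in at proportionally higher cell concentrations.
    Returns a DataFrame with strain_id, added_cells_per_ml and the common
    added_biovolume_um3_per_ml.
    """
    if factor <= 0:
        raise ValueError("addition factor must be positive")
    if background_conc < 0 or background_mcv <= 0:
        raise ValueError("background concentration/volume must be positive")
    bv_add = factor * background_conc * background_mcv
    rows = []
    for s in strains:
        if s.volume <= 0:
            raise ValueError(f"strain {s.strain_id} has non-positive volume")
        rows.append(
            {
                "strain_id": s.strain_id,
                "added_cells_per_ml": bv_add / s.volume,
                "added_biovolume_um3_per_ml": bv_add,
            }
        )
    return pd.DataFrame(rows)


def load_strain_table() -> pd.DataFrame:
    """Bundled prey-strain morphometry table.

    Widths are not direct measurements: the ``width_source == 'derived'``
    column marks them as back-computed from the published mean volume and
    length via W = sqrt(6V / (pi L)).
    """
    with resources.files("bacterivory.data").joinpath(
        "strain_morphometry.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def strains_from_table(df: pd.DataFrame) -> list[StrainSpec]:
    """Convert a strain-table DataFrame into StrainSpec objects."""
    return [
        StrainSpec(
            strain_id=r.strain_id,
            lineage=r.lineage,
            volume=float(r.volume_um3),
            length=float(r.length_um),
            shape=getattr(r, "shape", ""),
        )
        for r in df.itertuples(index=False)
    ]
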