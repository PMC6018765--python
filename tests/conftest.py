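import pandas as pd
import pytest
from hypothesis import settings

from bacterivory.io import abundance_frame_to_series

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def table3_groups() -> pd.DataFrame:
    """Published T0 flagellate group counts: abundances and vacuole contents."""
    return pd.DataFrame(
        {
            "group": ["All HNF", "All Crypto", "CRY1 lineage"],
            "abundance_per_ml": [5400.0, 3380.0, 100.0],
            "vacuole_bacteria_per_cell": [2.9, 3.1, 1.8],
            "is_community": [1, 0, 0],
        }
    )


def series_of(df: pd.DataFrame):
    """Convert one simulated treatment frame into its AbundanceSeries list."""
    by_treatment = abundance_frame_to_series(df)
    (reps,) = by_treatment.values()
    return reps
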