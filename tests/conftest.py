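import numpy as np
import pandas as pd
import pytest

from petdesync import default_atlas, default_config, generate_cohort


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """A compact two-genotype cohort used across modules (single timepoint)."""
    cfg = default_config(
        seed=7,
        n_per_arm={"WT PL/PL": 8, "WT Ab/PL": 6, "KI PL/PL": 8, "KI Ab/PL": 8},
        timepoints=(10.0,),
        missing_rate={},
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def longitudinal_cohort():
    """Three-timepoint cohort for baseline-change and missingness tests."""
    cfg = default_config(
        seed=11,
        n_per_arm={"WT PL/PL": 6, "WT Ab/PL": 6, "KI PL/PL": 10, "KI Ab/PL": 10},
        missing_rate={},
    )
    return generate_cohort(cfg)


def suvr_profiles(values: dict[str, list[float]], unit: str = "SUVR") -> pd.DataFrame:
    """Tiny hand-built long table: {voi: per-subject values} -> one-age table."""
    vois = list(values)
    n = len(values[vois[0]])
    rows = []
    for i in range(n):
        for v in vois:
            rows.append((f"s{i}", "WT", "PL/PL", 10.0, "TSPO", v,
                         values[v][i], unit))
    return pd.DataFrame(rows, columns=["subject_id", "genotype", "arm",
                                       "age_months", "tracer", "voi", "value",
                                       "unit"])
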