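import numpy as np
import pandas as pd
import pytest

from pa_concordance.accelerometry import MetSeries

MONDAY = pd.Timestamp("2024-03-04")


def make_series(met, wear=None, epoch_s=1, participant_id="P", week="T0", start=MONDAY):
    """Day-aligned MetSeries helper (pads nothing: met must span whole days)."""
    met = np.asarray(met, dtype=float)
    if wear is None:
        wear = np.ones(met.size, dtype=bool)
    return MetSeries(
        participant_id=participant_id,
        week=week,
        epoch_s=epoch_s,
        start=start,
        met=met,
        wear=np.asarray(wear, dtype=bool),
    )


@pytest.fixture(scope="session")
def small_cohort_dataset():
    """One small simulated cohort shared by read-only tests."""
    from pa_concordance import SimConfig, simulate_dataset

    cfg = SimConfig(n_adults=6, n_children=6, base_epoch_s=10, seed=42)
    return simulate_dataset(cfg)
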