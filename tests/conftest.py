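import datetime

import numpy as np
import pytest

from spectransfer import ExperimentParams, TrialConfig, generate_trial
from spectransfer.spectral import MeasurementDate


def make_dates(doys, stages=None, year=2020):
    """MeasurementDates for a list of DOYs (stages optional)."""
    stages = stages or [None] * len(doys)
    return [
        MeasurementDate(
            datetime.date(year, 1, 1) + datetime.timedelta(days=int(d) - 1), int(d), s
        )
        for d, s in zip(doys, stages)
    ]


@pytest.fixture(scope="session")
def small_campaign():
    """Two 80-plot trials, 3 dates each, same year, different locations."""
    common = dict(
        n_rows=10,
        n_plots_per_row=8,
        stage_by_date=[30, 65, 80],
        signal_curve=[0.3, 0.8, 0.4],
        missing_harvest_frac=0.1,
        pixels_per_plot=32,
    )
    a = generate_trial(
        TrialConfig("HZ", 2020, date_doys=[90, 120, 150], seed=11, **common)
    )
    b = generate_trial(
        TrialConfig("MR", 2020, date_doys=[95, 124, 146], seed=12, **common)
    )
    return {a.trial_id: a, b.trial_id: b}


@pytest.fixture()
def relaxed_params():
    """Experiment params workable at the small fixtures' plot counts."""
    return ExperimentParams(min_train_plots=20)
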