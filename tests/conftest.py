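import datetime as dt

import pytest

from sleepspan.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact but fully featured cohort: 5 participants, ~3 months, DST inside."""
    cfg = SyntheticConfig(
        n_participants=5,
        enrollment_start=dt.date(2017, 9, 20),
        enrollment_end=dt.date(2017, 10, 1),
        study_end=dt.date(2017, 12, 28),
        seed=11,
    )
    panel, truth = generate_cohort(cfg, seed=11)
    return cfg, panel, truth


@pytest.fixture()
def small_panel(small_cohort):
    return small_cohort[1]
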