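import numpy as np
import pandas as pd
import pytest

from mscure import Cohort, FitConfig, default_truth, fit, generate_cohort


def make_cohort(rows):
    """Build a cohort from (id, age, sex, stage, meta, chemo, bmi, t_rec,
    d_rec, t_death, d_death) tuples."""
    cols = ("id", "age", "sex", "stage", "metastasis", "chemotherapy",
            "bmi", "t_rec", "d_rec", "t_death", "d_death")
    return Cohort.from_records([dict(zip(cols, r)) for r in rows])


@pytest.fixture(scope="session")
def toy_cohort():
    """Three hand-written subjects: one recurrence+death, one death
    without recurrence, one censored alive."""
    return make_cohort([
        ("a", 60.0, "female", "II", "no", "yes", 24.0, 12.0, 1, 30.0, 1),
        ("b", 70.0, "male", "IV", "yes", "yes", None, 8.0, 0, 8.0, 1),
        ("c", 50.0, "female", "III", "no", "no", 22.0, 55.0, 0, 55.0, 0),
    ])


@pytest.fixture(scope="session")
def small_cohort():
    cohort, latent = generate_cohort(300, default_truth(), seed=11)
    return cohort


@pytest.fixture(scope="session")
def small_latent():
    return generate_cohort(300, default_truth(), seed=11)[1]


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """One EM fit shared by prediction/reporting tests."""
    return fit(small_cohort, FitConfig(n_boot=0, center_age=55.58))
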