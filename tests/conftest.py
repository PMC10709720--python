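"""Shared fixtures: toy survival data, small simulated cohorts, and one
session-scoped fitted model reused across the model/recommendation/
evaluation tests to keep the suite fast."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import bslsurv as bs
from bslsurv.model import BSLConfig, fit_bsl


@pytest.fixture(scope="session")
def toy_survival():
    """Two subjects, both events, at t = 1 and 2 (classic hand example)."""
    return np.array([1.0, 2.0]), np.array([1, 1])


@pytest.fixture(scope="session")
def small_cohort():
    """Default-process cohort, n=2,500, with ground truth."""
    cohort, gt = bs.generate_cohort(bs.default_config(n=2500, seed=11))
    return cohort, gt


@pytest.fixture(scope="session")
def small_design(small_cohort):
    cohort, gt = small_cohort
    return bs.encode_design(cohort), gt


@pytest.fixture(scope="session")
def fitted_bsl(small_design):
    """A quickly-trained BSL on 2,000 patients (500 held out)."""
    dm, gt = small_design
    train, test, tr_idx, te_idx = bs.split_train_test(dm, 0.2, seed=5)
    model = fit_bsl(train, BSLConfig(seed=5, epochs=30, cv_folds=2))
    return model, train, test, te_idx, gt


def toy_cohort_frame():
    """Six hand-written patients exercising every filter rule."""
    base = dict(sex="male", marital="married", income="low", area="urban",
                region="west", histology="astrocytoma", location="frontal",
                laterality="left", extension="confined")
    rows = [
        dict(patient_id="A", age=50, tumor_size=30, treatment=1, time=24.0, event=1, **base),
        dict(patient_id="B", age=40, tumor_size=22, treatment=0, time=60.0, event=0, **base),
        dict(patient_id="C", age=33, tumor_size=15, treatment=1, time=12.0, event=1, **base),
        dict(patient_id="A", age=50, tumor_size=30, treatment=1, time=24.0, event=1, **base),  # duplicate id
        dict(patient_id="D", age=17, tumor_size=18, treatment=0, time=36.0, event=0, **base),  # minor
        dict(patient_id="E", age=61, tumor_size=40, treatment=0, time=48.0, event=1, **base),
    ]
    df = pd.DataFrame(rows)
    df.loc[df.patient_id == "E", "laterality"] = "unknown"
    return df


@pytest.fixture()
def toy_cohort_csv(tmp_path):
    path = tmp_path / "toy.csv"
    toy_cohort_frame().to_csv(path, index=False)
    return path
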