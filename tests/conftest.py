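"""Shared fixtures: record builders, packaged tables, a small synthetic run."""

from __future__ import annotations

import pytest
from hypothesis import settings

from octostrat import fixtures as fx
from octostrat.hypotheses import build_registry
from octostrat.model import PatientRecord
from octostrat.simulate import SyntheticConfig, generate_dataset

settings.register_profile("ci", max_examples=100, derandomize=True, deadline=None)
settings.load_profile("ci")


def make_record(**overrides) -> PatientRecord:
    """A valid baseline record with sensible defaults, field overrides on top."""
    base = dict(
        patient_id="P001",
        cohort_id="AMS_OA",
        sex="female",
        age=63.0,
        kl_grade=2,
        bmi=27.5,
        strength_instrument="isokinetic",
        strength_baseline=0.9,
        pain_baseline_raw=6.0,
        pain_scale="nrs_0_10",
        womac_pf_baseline=45.0,
        exercise_arm=False,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture(scope="session")
def proportion_table():
    return fx.load_proportion_table()


@pytest.fixture(scope="session")
def table4_summary():
    return fx.load_table4_summary()


@pytest.fixture(scope="session")
def table5_effects():
    return fx.load_table5_effects()


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture(scope="session")
def small_synthetic():
    """One study-sized synthetic dataset (1211 records), reused read-only."""
    config = SyntheticConfig.default()
    records, truth = generate_dataset(config, seed=20240915)
    return config, records, truth
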