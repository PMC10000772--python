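"""Shared fixtures and small hand-built claims-table factories."""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from artclaims import CohortSpec, GeneratorConfig, generate_cohort_tables
from artclaims.synthetic_claims import (
    ClaimsTables,
    DEMOGRAPHICS_COLUMNS,
    GROUND_TRUTH_COLUMNS,
    HOSPITAL_COLUMNS,
    OUTPATIENT_COLUMNS,
    PHARMACY_COLUMNS,
    _DATE_COLUMNS,
)

_DEFAULTS = {
    "demographics": {
        "sex": "M",
        "birth_date": "1970-06-15",
        "enrollment_start": "2014-01-01",
        "enrollment_end": "2020-12-31",
        "death_date": None,
        "transfer_out_date": None,
    },
    "pharmacy": {"n_packages": 1, "units_per_package": 30, "cost_eur": 100.0},
    "hospital": {"icd9_codes": "5409", "drg_code": "127", "tariff_eur": 1000.0},
    "outpatient": {"service_type": "visit", "tariff_eur": 30.0},
}
_COLUMNS = {
    "demographics": DEMOGRAPHICS_COLUMNS,
    "pharmacy": PHARMACY_COLUMNS,
    "hospital": HOSPITAL_COLUMNS,
    "outpatient": OUTPATIENT_COLUMNS,
    "ground_truth": GROUND_TRUTH_COLUMNS,
}


def make_tables(demographics, pharmacy=(), hospital=(), outpatient=()) -> ClaimsTables:
    """Build a ClaimsTables from lists of partial row dicts."""
    frames = {}
    for name, rows in [
        ("demographics", demographics), ("pharmacy", pharmacy),
        ("hospital", hospital), ("outpatient", outpatient),
        ("ground_truth", ()),
    ]:
        full = [{**_DEFAULTS.get(name, {}), **r} for r in rows]
        df = pd.DataFrame(full, columns=_COLUMNS[name])
        for col in _DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col])
        frames[name] = df
    return ClaimsTables(**frames)


def monthly_dispensations(pid, start, n, atc="J05AR20", step=30, **kw):
    start = pd.Timestamp(start)
    return [
        {"patient_id": pid, "atc_code": atc,
         "dispensation_date": start + pd.Timedelta(days=step * i), **kw}
        for i in range(n)
    ]


def pdc_calendar_oracle(days, supplies, window_days) -> float:
    """Day-by-day inventory simulation of PDC (independent oracle).

    Supply is banked when dispensed and one unit is consumed per day while
    any stock is on hand, which reproduces carry-forward stockpiling
    without interval arithmetic.
    """
    add = defaultdict(int)
    for d, s in zip(days, supplies):
        if d >= 0:
            add[int(d)] += int(s)
    stock = covered = 0
    for day in range(window_days):
        stock += add.get(day, 0)
        if stock > 0:
            covered += 1
            stock -= 1
    return 100.0 * covered / window_days


def random_stream(rng, max_disp=12, window=365):
    n = int(rng.integers(0, max_disp + 1))
    days = rng.integers(-30, window + 30, size=n)
    supplies = rng.integers(1, 61, size=n)
    return days, supplies, window


@pytest.fixture(scope="session")
def default_spec() -> CohortSpec:
    return CohortSpec()


@pytest.fixture(scope="session")
def gen_tables():
    """A medium synthetic extraction shared across read-only tests."""
    return generate_cohort_tables(GeneratorConfig(n_patients=400, seed=11))
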