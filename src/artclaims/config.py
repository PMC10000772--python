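"""Configuration objects and drug/diagnosis code tables.

The ATC codes identifying tenofovir-alafenamide (TAF) regimens, the
single-tablet-regimen (STR) subset, and the HIV-related DRG codes are fixed
study constants. The comorbidity ATC/ICD-9-CM lists and the Charlson (Deyo)
category table are editable configuration: administrative-claims studies
differ in exactly which codes identify a condition, so the defaults here are
a documented, reasonable choice rather than a canonical one.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

# --- study constants -------------------------------------------------------

ART_ATC_PREFIXES: tuple[str, ...] = ("J05A",)

#: TAF-containing products (TAF alone, FTC/TAF backbone, and the four
#: complete fixed-dose combinations).
TAF_ATC_CODES: frozenset[str] = frozenset(
    {"J05AF13", "J05AR17", "J05AR18", "J05AR19", "J05AR20", "J05AR22"}
)

#: Complete single-tablet regimens; J05AF13/J05AR17 require a concomitant
#: third agent and are treated as multi-tablet regimens (MTR).
STR_ATC_CODES: frozenset[str] = frozenset(
    {"J05AR18", "J05AR19", "J05AR20", "J05AR22"}
)

#: DRG codes counted as HIV-related hospitalizations.
HIV_DRG_CODES: frozenset[str] = frozenset({"488", "489", "490"})

DEFAULT_NON_HIV_DRGS: tuple[str, ...] = (
    "014", "089", "127", "183", "243", "316", "410", "467",
)


class CodeSet(BaseModel):
    """ATC prefixes and ICD-9-CM prefixes identifying one condition.

    Matching is prefix-based on dot-stripped codes, e.g. ``"250"`` matches
    ``250.02``.
    """

    atc: tuple[str, ...] = ()
    icd9: tuple[str, ...] = ()


#: Baseline comorbidities evaluated in the characterization year.
DEFAULT_COMORBIDITY_CODES: dict[str, CodeSet] = {
    "depression": CodeSet(atc=("N06A",), icd9=("2962", "2963", "311")),
    "respiratory_disease": CodeSet(
        atc=("R03",), icd9=("490", "491", "492", "493", "494", "496")
    ),
    "renal_failure": CodeSet(icd9=("585", "586")),
    "alcohol_drug_abuse": CodeSet(icd9=("303", "304", "3050")),
    "cardiovascular_disease": CodeSet(
        atc=("C01",), icd9=("410", "411", "414", "428")
    ),
    "cancer": CodeSet(
        icd9=("153", "162", "174", "185", "196", "197", "198", "199")
    ),
    "diabetes": CodeSet(atc=("A10",), icd9=("250",)),
    "dyslipidemia": CodeSet(atc=("C10",), icd9=("272",)),
    "hbv_hcv": CodeSet(icd9=("070",)),
    "hypertension": CodeSet(
        atc=("C02", "C03", "C09"), icd9=("401", "402", "403", "404", "405")
    ),
}


class CciCategory(BaseModel):
    """One Charlson category: ICD-9-CM prefixes, weight, hierarchy."""

    icd9: tuple[str, ...]
    weight: int
    supersedes: tuple[str, ...] = ()


#: Deyo ICD-9-CM mapping of the Charlson index. The HIV/AIDS item is kept in
#: the table but carries weight 0: the score deliberately does not count HIV
#: in an all-HIV cohort.
DEFAULT_CCI_CATEGORIES: dict[str, CciCategory] = {
    "myocardial_infarction": CciCategory(icd9=("410", "412"), weight=1),
    "congestive_heart_failure": CciCategory(icd9=("428",), weight=1),
    "peripheral_vascular": CciCategory(
        icd9=("441", "4439", "7854", "V434"), weight=1
    ),
    "cerebrovascular": CciCategory(
        icd9=("430", "431", "432", "433", "434", "435", "436", "437", "438"),
        weight=1,
    ),
    "dementia": CciCategory(icd9=("290",), weight=1),
    "chronic_pulmonary": CciCategory(
        icd9=("490", "491", "492", "493", "494", "495", "496",
              "500", "501", "502", "503", "504", "505"),
        weight=1,
    ),
    "rheumatic": CciCategory(
        icd9=("7100", "7101", "7104", "7140", "7141", "7142", "725"), weight=1
    ),
    "peptic_ulcer": CciCategory(icd9=("531", "532", "533", "534"), weight=1),
    "mild_liver_disease": CciCategory(
        icd9=("070", "5712", "5714", "5715", "5716"), weight=1
    ),
    "diabetes": CciCategory(
        icd9=("2500", "2501", "2502", "2503", "2507"), weight=1
    ),
    "diabetes_complications": CciCategory(
        icd9=("2504", "2505", "2506"), weight=2, supersedes=("diabetes",)
    ),
    "hemiplegia": CciCategory(icd9=("342", "3441"), weight=2),
    "renal_disease": CciCategory(
        icd9=("582", "583", "585", "586", "588"), weight=2
    ),
    "any_malignancy": CciCategory(
        icd9=("14", "15", "16", "170", "171", "172", "174", "175", "176",
              "179", "18", "190", "191", "192", "193", "194", "195",
              "200", "201", "202", "203", "204", "205", "206", "207", "208"),
        weight=2,
    ),
    "metastatic_tumor": CciCategory(
        icd9=("196", "197", "198", "199"), weight=6,
        supersedes=("any_malignancy",),
    ),
    "severe_liver_disease": CciCategory(
        icd9=("4560", "4561", "4562", "5722", "5723", "5724", "5728"),
        weight=3, supersedes=("mild_liver_disease",),
    ),
    "hiv": CciCategory(icd9=("042", "043", "044"), weight=0),
}


# --- generator configuration ----------------------------------------------


class GammaParams(BaseModel):
    """Shape/scale of a gamma cost distribution (EUR)."""

    shape: float = Field(gt=0)
    scale: float = Field(gt=0)

    @property
    def mean(self) -> float:
        return self.shape * self.scale


class MixtureComponent(BaseModel):
    """Uniform component of the per-patient target-PDC mixture."""

    weight: float = Field(gt=0)
    low: float = Field(ge=0.0, le=1.0)
    high: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _ordered(self) -> "MixtureComponent":
        if self.low > self.high:
            raise ValueError("mixture component needs low <= high")
        return self


class PdcMixture(BaseModel):
    components: tuple[MixtureComponent, ...]

    @model_validator(mode="after")
    def _nonempty(self) -> "PdcMixture":
        if not self.components:
            raise ValueError("mixture needs at least one component")
        return self

    @property
    def mean(self) -> float:
        w = np.array([c.weight for c in self.components])
        m = np.array([(c.low + c.high) / 2 for c in self.components])
        return float((w * m).sum() / w.sum())

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        w = np.array([c.weight for c in self.components], dtype=float)
        idx = rng.choice(len(w), size=n, p=w / w.sum())
        lo = np.array([c.low for c in self.components])[idx]
        hi = np.array([c.high for c in self.components])[idx]
        return lo + rng.random(n) * (hi - lo)


#: Default target-PDC mixture: 83.3% of patients above the 0.95 adherence
#: cut-off, 90.6% above 0.85, remainder spread over low coverage.
DEFAULT_PDC_MIXTURE = PdcMixture(
    components=(
        MixtureComponent(weight=0.833, low=0.96, high=1.0),
        MixtureComponent(weight=0.073, low=0.86, high=0.95),
        MixtureComponent(weight=0.094, low=0.40, high=0.85),
    )
)

DEFAULT_COST_PARAMS: dict[str, GammaParams] = {
    # per ART dispensation
    "hiv_drugs": GammaParams(shape=50.0, scale=12.8),
    # per non-ART dispensation
    "other_drugs": GammaParams(shape=2.0, scale=40.0),
    # per HIV-related admission, by persistence of the patient
    "hiv_hosp_persistent": GammaParams(shape=2.0, scale=1224.0),
    "hiv_hosp_nonpersistent": GammaParams(shape=2.0, scale=2998.0),
    # per other-cause admission
    "other_hosp": GammaParams(shape=2.0, scale=1500.0),
    # per outpatient service
    "outpatient": GammaParams(shape=2.0, scale=22.5),
}

DEFAULT_COMORBIDITY_PREVALENCES: dict[str, float] = {
    "depression": 0.074,
    "respiratory_disease": 0.159,
    "renal_failure": 0.013,
    "alcohol_drug_abuse": 0.039,
    "cardiovascular_disease": 0.024,
    "cancer": 0.037,
    "diabetes": 0.035,
    "dyslipidemia": 0.112,
    "hbv_hcv": 0.078,
    "hypertension": 0.195,
}


class GeneratorConfig(BaseModel):
    """Study conditions for the synthetic-claims generator.

    Defaults reproduce the margins of the reference cohort: a 2658-patient
    ART population of which ~45% receive a TAF-based regimen, 71.6% male,
    age 48.6 +/- 11 years, 78.5% persistent / 17.5% switching / 4%
    discontinuing, and a target-PDC mixture putting 83.3% of patients above
    the 95% adherence threshold.
    """

    n_patients: int = Field(default=2658, ge=0)
    male_fraction: float = Field(default=0.716, ge=0, le=1)
    age_mean: float = 48.6
    age_sd: float = Field(default=11.0, gt=0)
    age_min: float = 19.0
    age_max: float = 90.0
    comorbidity_prevalences: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCES)
    )
    taf_fraction: float = Field(default=0.4507, ge=0, le=1)
    str_fraction_given_taf: float = Field(default=0.571, ge=0, le=1)
    naive_fraction_given_taf: float = Field(default=0.399, ge=0, le=1)
    pdc_target_distribution: PdcMixture = DEFAULT_PDC_MIXTURE
    persistence_prob: float = Field(default=0.785, ge=0, le=1)
    switch_prob: float = Field(default=0.175, ge=0, le=1)
    units_per_package: int = Field(default=30, ge=1)
    packages_per_dispensation: int = Field(default=1, ge=1)
    other_drug_rate: float = Field(default=10.0, ge=0)  # dispensations / PY
    other_hosp_rate: float = Field(default=0.05, ge=0)  # admissions / PY
    outpatient_rate: float = Field(default=8.0, ge=0)  # services / PY
    hiv_hosp_rate_persistent: float = Field(default=0.088, ge=0)
    hiv_hosp_rate_nonpersistent: float = Field(default=0.102, ge=0)
    death_rate: float = Field(default=0.01, ge=0)  # deaths / PY
    transfer_fraction: float = Field(default=0.01, ge=0, le=1)
    drug_evidence_prob: float = Field(default=0.75, ge=0, le=1)
    cost_params: dict[str, GammaParams] = Field(
        default_factory=lambda: dict(DEFAULT_COST_PARAMS)
    )
    non_hiv_drgs: tuple[str, ...] = DEFAULT_NON_HIV_DRGS
    seed: int = 0
    study_start: dt.date = dt.date(2014, 1, 1)
    inclusion_start: dt.date = dt.date(2015, 1, 1)
    inclusion_end: dt.date = dt.date(2019, 12, 31)
    study_end: dt.date = dt.date(2020, 12, 31)

    @field_validator("comorbidity_prevalences")
    @classmethod
    def _prev_in_unit(cls, v: dict[str, float]) -> dict[str, float]:
        for k, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {k} outside [0, 1]")
        return v

    @model_validator(mode="after")
    def _consistent(self) -> "GeneratorConfig":
        if not (
            self.study_start <= self.inclusion_start
            <= self.inclusion_end <= self.study_end
        ):
            raise ValueError(
                "dates must satisfy study_start <= inclusion_start <= "
                "inclusion_end <= study_end"
            )
        if self.persistence_prob + self.switch_prob > 1 + 1e-12:
            raise ValueError(
                "persistence_prob + switch_prob must not exceed 1"
            )
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be below age_max")
        missing = set(self.comorbidity_prevalences) - set(
            DEFAULT_COMORBIDITY_CODES
        )
        if missing:
            raise ValueError(f"unknown comorbidity keys: {sorted(missing)}")
        return self

    @property
    def days_supplied(self) -> int:
        return self.units_per_package * self.packages_per_dispensation


# --- cohort specification ---------------------------------------------------


class CohortSpec(BaseModel):
    """Screening, inclusion/exclusion and characterization rules."""

    art_atc_prefixes: tuple[str, ...] = ART_ATC_PREFIXES
    taf_atc_codes: frozenset[str] = TAF_ATC_CODES
    str_atc_codes: frozenset[str] = STR_ATC_CODES
    hiv_drg_codes: frozenset[str] = HIV_DRG_CODES
    inclusion_start: dt.date = dt.date(2015, 1, 1)
    inclusion_end: dt.date = dt.date(2019, 12, 31)
    min_age: int = Field(default=18, ge=0)
    lookback_days: int = Field(default=365, gt=0)
    max_gap_days: int = Field(default=365, gt=0)
    min_followup_days: int = Field(default=365, gt=0)
    comorbidity_code_map: dict[str, CodeSet] = Field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_CODES)
    )
    cci_categories: dict[str, CciCategory] = Field(
        default_factory=lambda: dict(DEFAULT_CCI_CATEGORIES)
    )
    #: presence in the last quarter judged by dispensation date (default) or
    #: by supply coverage overlapping the window
    persistence_rule: str = "date_in_window"
    #: last quarter of year 1 (default) or of all available follow-up
    quarter_basis: str = "first_year"

    @model_validator(mode="after")
    def _consistent(self) -> "CohortSpec":
        if not self.taf_atc_codes >= self.str_atc_codes:
            raise ValueError("STR codes must be a subset of TAF codes")
        if self.inclusion_start > self.inclusion_end:
            raise ValueError("inclusion_start must precede inclusion_end")
        if self.persistence_rule not in {"date_in_window", "coverage_in_window"}:
            raise ValueError(f"unknown persistence_rule {self.persistence_rule}")
        if self.quarter_basis not in {"first_year", "all_followup"}:
            raise ValueError(f"unknown quarter_basis {self.quarter_basis}")
        return self


def load_generator_config(path) -> GeneratorConfig:
    """Read a :class:`GeneratorConfig` from a YAML file."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return GeneratorConfig(**payload)


def load_cohort_spec(path) -> CohortSpec:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return CohortSpec(**payload)
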