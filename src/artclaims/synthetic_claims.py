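"""Synthetic linked administrative-claims tables with known ground truth.

Emulates the four databases an Italian Local Health Unit would link by
anonymous patient ID: demographics, pharmacy dispensations, hospital
discharges and outpatient services. The generator plants, per patient, a
target proportion-of-days-covered (PDC), a persistence / switch /
discontinuation label, a regimen class (single- vs multi-tablet TAF, or
non-TAF ART) and baseline comorbidities, then emits event streams that the
downstream pipeline should recover. The planted values are returned in a
fifth ``ground_truth`` table so parameter-recovery tests need no real data.

Randomness is split per patient with :class:`numpy.random.SeedSequence`
(stream i = child i of the master seed), so any patient's records can be
regenerated in isolation and tables are byte-identical across runs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GeneratorConfig

#: last quarter of the first follow-up year, in days since index
LAST_QUARTER = (274, 365)

#: non-TAF ART combination products used for prior therapy, switch targets
#: and the non-TAF arm of the cohort
NON_TAF_ART_CODES = ("J05AR06", "J05AR10", "J05AR13", "J05AX12")

#: third agents dispensed alongside an MTR backbone (ART, not TAF)
MTR_THIRD_AGENTS = ("J05AX12", "J05AG03")

MTR_BACKBONES = ("J05AF13", "J05AR17")
STR_PRODUCTS = ("J05AR18", "J05AR19", "J05AR20", "J05AR22")

#: concrete codes emitted as baseline-comorbidity evidence; they fall under
#: the prefix sets of config.DEFAULT_COMORBIDITY_CODES
_ATC_EVIDENCE = {
    "depression": ("N06AB06", "N06AX16"),
    "respiratory_disease": ("R03AC02", "R03BB04"),
    "cardiovascular_disease": ("C01DA14",),
    "diabetes": ("A10BA02", "A10BB12"),
    "dyslipidemia": ("C10AA05",),
    "hypertension": ("C09AA02", "C03CA01", "C02AC01"),
}
_ICD_EVIDENCE = {
    "depression": ("311",),
    "respiratory_disease": ("4919", "49390"),
    "renal_failure": ("5859", "586"),
    "alcohol_drug_abuse": ("3039", "3049"),
    "cardiovascular_disease": ("4280", "41401"),
    "cancer": ("1629", "1749", "1859"),
    "diabetes": ("25000",),
    "dyslipidemia": ("2720", "2724"),
    "hbv_hcv": ("07054", "07032"),
    "hypertension": ("4019",),
}
_METASTATIC_ICD = "1970"

_OTHER_DRUG_ATCS = ("A02BC02", "B01AC06", "J01CA04", "M01AE01", "N02BE01")

PHARMACY_COLUMNS = [
    "patient_id", "atc_code", "dispensation_date",
    "n_packages", "units_per_package", "cost_eur",
]
DEMOGRAPHICS_COLUMNS = [
    "patient_id", "sex", "birth_date", "enrollment_start", "enrollment_end",
    "death_date", "transfer_out_date",
]
HOSPITAL_COLUMNS = [
    "patient_id", "admission_date", "discharge_date",
    "icd9_codes", "drg_code", "tariff_eur",
]
OUTPATIENT_COLUMNS = ["patient_id", "service_date", "service_type", "tariff_eur"]
GROUND_TRUTH_COLUMNS = [
    "patient_id", "is_taf", "regimen", "experience", "status",
    "target_pdc", "index_date",
]

_DATE_COLUMNS = {
    "demographics": ["birth_date", "enrollment_start", "enrollment_end",
                     "death_date", "transfer_out_date"],
    "pharmacy": ["dispensation_date"],
    "hospital": ["admission_date", "discharge_date"],
    "outpatient": ["service_date"],
    "ground_truth": ["index_date"],
}
TABLE_NAMES = ["demographics", "pharmacy", "hospital", "outpatient",
               "ground_truth"]
_STR_COLUMNS = {
    "demographics": ["patient_id", "sex"],
    "pharmacy": ["patient_id", "atc_code"],
    "hospital": ["patient_id", "icd9_codes", "drg_code"],
    "outpatient": ["patient_id", "service_type"],
    "ground_truth": ["patient_id", "regimen", "experience", "status"],
}


@dataclass
class ClaimsTables:
    """The four linked tables plus the generator's ground truth."""

    demographics: pd.DataFrame
    pharmacy: pd.DataFrame
    hospital: pd.DataFrame
    outpatient: pd.DataFrame
    ground_truth: pd.DataFrame

    def table_names(self) -> list[str]:
        return [f.name for f in fields(self)]


def _refill_days(
    rng: np.random.Generator,
    target_pdc: float,
    start: int,
    stop: int,
    supply: int,
) -> list[int]:
    """Dispensation days of a refill process realizing ``target_pdc``.

    Each refill is delayed past the end of the previous supply by a
    geometric number of uncovered days with mean ``supply*(1-p)/p``, which
    makes the long-run covered fraction equal the target.
    """
    p = min(max(target_pdc, 0.05), 1.0)
    mean_gap = supply * (1.0 - p) / p
    days: list[int] = []
    d = start
    while d < stop:
        days.append(d)
        extra = 0
        if mean_gap > 0:
            extra = int(rng.geometric(1.0 / (1.0 + mean_gap))) - 1
        d += supply + extra
    return days


def _pick(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


def _ensure_window_refill(
    rng: np.random.Generator, days: list[int], horizon: int
) -> list[int]:
    """Guarantee one dispensation date in the last quarter of year 1."""
    lo, hi = LAST_QUARTER
    if horizon < hi:
        return days
    if not any(lo <= d < hi for d in days):
        days = sorted(days + [int(rng.integers(lo, hi))])
    return days


def generate_cohort_tables(config: GeneratorConfig) -> ClaimsTables:
    """Generate the linked tables for ``config.n_patients`` ART patients."""
    cfg = config
    master = np.random.SeedSequence(cfg.seed)
    streams = master.spawn(cfg.n_patients)

    demo_rows: list[tuple] = []
    pharm_rows: list[tuple] = []
    hosp_rows: list[tuple] = []
    outp_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    supply = cfg.days_supplied
    incl_span = (cfg.inclusion_end - cfg.inclusion_start).days + 1
    comorb_items = sorted(cfg.comorbidity_prevalences.items())
    # hoisted scalars: pydantic attribute access is too slow for the loop
    cost_p = {k: (v.shape, v.scale) for k, v in cfg.cost_params.items()}
    n_pack, n_units = cfg.packages_per_dispensation, cfg.units_per_package
    mix = cfg.pdc_target_distribution.components
    mix_cum = np.cumsum([c.weight for c in mix])
    mix_cum = mix_cum / mix_cum[-1]
    mix_lo = [c.low for c in mix]
    mix_span = [c.high - c.low for c in mix]
    study_end = cfg.study_end

    for i in range(cfg.n_patients):
        rng = np.random.default_rng(streams[i])
        pid = f"P{i:06d}"

        sex = "M" if rng.random() < cfg.male_fraction else "F"
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd),
                            cfg.age_min, cfg.age_max))
        index_date = cfg.inclusion_start + dt.timedelta(
            days=int(rng.integers(0, incl_span))
        )
        birth_date = index_date - dt.timedelta(days=int(round(age * 365.25)))
        followup_days = (study_end - index_date).days

        death_day: int | None = None
        if cfg.death_rate > 0:
            t = rng.exponential(365.25 / cfg.death_rate)
            if t < followup_days:
                death_day = max(1, int(t))
        transfer_day: int | None = None
        if rng.random() < cfg.transfer_fraction:
            transfer_day = int(rng.integers(30, followup_days + 1))
        horizon = min(
            followup_days,
            death_day if death_day is not None else followup_days,
            transfer_day if transfer_day is not None else followup_days,
        )

        is_taf = rng.random() < cfg.taf_fraction
        k = int(np.searchsorted(mix_cum, rng.random(), side="right"))
        k = min(k, len(mix) - 1)
        target_pdc = mix_lo[k] + rng.random() * mix_span[k]

        def hosp(adm_day: int, los: int, icd: str, drg: str, cost_key: str) -> None:
            adm = index_date + dt.timedelta(days=int(adm_day))
            dis = min(adm + dt.timedelta(days=int(los)), study_end)
            sh, sc = cost_p[cost_key]
            hosp_rows.append((
                pid, adm, dis, icd, drg, round(float(rng.gamma(sh, sc)), 2),
            ))

        def disp(day: int, atc: str, cost_key: str = "hiv_drugs") -> None:
            sh, sc = cost_p[cost_key]
            pharm_rows.append((
                pid, atc, index_date + dt.timedelta(days=int(day)),
                n_pack, n_units, round(float(rng.gamma(sh, sc)), 2),
            ))

        if is_taf:
            regimen = "STR" if rng.random() < cfg.str_fraction_given_taf else "MTR"
            experience = ("naive" if rng.random() < cfg.naive_fraction_given_taf
                          else "switcher")
            u = rng.random()
            if u < cfg.persistence_prob:
                status = "persistent"
            elif u < cfg.persistence_prob + cfg.switch_prob:
                status = "switched"
            else:
                status = "discontinued"

            if regimen == "STR":
                taf_atc = _pick(rng, STR_PRODUCTS)
                third_atc = None
            else:
                taf_atc = _pick(rng, MTR_BACKBONES)
                third_atc = _pick(rng, MTR_THIRD_AGENTS)

            if status == "persistent":
                taf_days = _refill_days(rng, target_pdc, 0, horizon, supply)
                taf_days = _ensure_window_refill(rng, taf_days, horizon)
            elif status == "switched":
                t_switch = int(rng.integers(90, 241))
                taf_days = _refill_days(
                    rng, target_pdc, 0, min(t_switch, horizon), supply
                )
                if len(taf_days) < 2:
                    taf_days.append(min(t_switch, horizon) - 1)
                start2 = t_switch + int(rng.integers(10, 61))
                switch_atc = _pick(rng, NON_TAF_ART_CODES)
                other_days = _refill_days(rng, target_pdc, start2, horizon, supply)
                other_days = _ensure_window_refill(rng, other_days, horizon)
                for d in other_days:
                    disp(d, switch_atc)
            else:  # discontinued: nothing after the stop, well before day 274
                t_stop = int(rng.integers(90, 241))
                taf_days = _refill_days(
                    rng, target_pdc, 0, min(t_stop, horizon), supply
                )
                if len(taf_days) < 2:
                    taf_days.append(min(t_stop, horizon) - 1)
            for d in sorted(set(taf_days)):
                disp(d, taf_atc)
                if third_atc is not None:
                    disp(d, third_atc)

            if experience == "switcher":
                prev_atc = _pick(rng, NON_TAF_ART_CODES)
                last_gap = int(rng.integers(5, 41))
                d = -365 + int(rng.integers(0, 15))
                while d < -last_gap:
                    disp(d, prev_atc)
                    d += supply + int(rng.integers(0, 10))
        else:
            regimen = "non_taf"
            experience = "none"
            status = "persistent"
            atc = _pick(rng, NON_TAF_ART_CODES)
            days = _refill_days(rng, target_pdc, 0, horizon, supply)
            days = _ensure_window_refill(rng, days, horizon)
            for d in days:
                disp(d, atc)

        # baseline comorbidity evidence in the characterization year
        flags = {}
        for cond, prev in comorb_items:
            flags[cond] = rng.random() < prev
            if not flags[cond]:
                continue
            atc_opts = _ATC_EVIDENCE.get(cond)
            if atc_opts and rng.random() < cfg.drug_evidence_prob:
                for _ in range(int(rng.integers(1, 3))):
                    day = -int(rng.integers(1, 366))
                    disp(day, _pick(rng, atc_opts), "other_drugs")
            else:
                if cond == "cancer" and rng.random() < 0.15:
                    icd = _METASTATIC_ICD
                else:
                    icd = _pick(rng, _ICD_EVIDENCE[cond])
                hosp(-int(rng.integers(10, 366)), int(rng.integers(2, 11)),
                     icd, _pick(rng, cfg.non_hiv_drgs), "other_hosp")

        # post-index hospitalizations
        py = horizon / 365.25
        hiv_rate = (cfg.hiv_hosp_rate_persistent if status == "persistent"
                    else cfg.hiv_hosp_rate_nonpersistent)
        hiv_key = ("hiv_hosp_persistent" if status == "persistent"
                   else "hiv_hosp_nonpersistent")
        for _ in range(int(rng.poisson(hiv_rate * py))):
            hosp(int(rng.integers(0, max(horizon, 1))),
                 int(rng.integers(3, 16)), "042",
                 _pick(rng, ("488", "489", "490")), hiv_key)
        for _ in range(int(rng.poisson(cfg.other_hosp_rate * py))):
            hosp(int(rng.integers(0, max(horizon, 1))),
                 int(rng.integers(2, 11)), "5409",
                 _pick(rng, cfg.non_hiv_drgs), "other_hosp")

        # non-ART drugs and outpatient services (batched draws)
        n_od = int(rng.poisson(cfg.other_drug_rate * py))
        if n_od:
            od_days = rng.integers(0, max(horizon, 1), size=n_od)
            od_atc = rng.integers(0, len(_OTHER_DRUG_ATCS), size=n_od)
            sh, sc = cost_p["other_drugs"]
            od_cost = np.round(rng.gamma(sh, sc, size=n_od), 2)
            for d, a, c in zip(od_days, od_atc, od_cost):
                pharm_rows.append((
                    pid, _OTHER_DRUG_ATCS[a],
                    index_date + dt.timedelta(days=int(d)),
                    n_pack, n_units, float(c),
                ))
        n_outp = int(rng.poisson(cfg.outpatient_rate * (py + 1.0)))
        if n_outp:
            op_days = rng.integers(-365, max(horizon, 1), size=n_outp)
            op_visit = rng.random(n_outp) < 0.5
            sh, sc = cost_p["outpatient"]
            op_cost = np.round(rng.gamma(sh, sc, size=n_outp), 2)
            for d, v, c in zip(op_days, op_visit, op_cost):
                outp_rows.append((
                    pid, index_date + dt.timedelta(days=int(d)),
                    "visit" if v else "diagnostic_test", float(c),
                ))

        enrollment_end = cfg.study_end
        death_date = None
        transfer_date = None
        if transfer_day is not None and transfer_day == horizon:
            transfer_date = index_date + dt.timedelta(days=transfer_day)
            enrollment_end = transfer_date
        if death_day is not None and death_day == horizon:
            death_date = index_date + dt.timedelta(days=death_day)
            enrollment_end = death_date
            transfer_date = None
        demo_rows.append((
            pid, sex, birth_date, cfg.study_start, enrollment_end,
            death_date, transfer_date,
        ))
        truth_rows.append((
            pid, is_taf, regimen, experience, status,
            round(target_pdc, 6), index_date,
        ))

    demographics = pd.DataFrame(demo_rows, columns=DEMOGRAPHICS_COLUMNS)
    pharmacy = pd.DataFrame(pharm_rows, columns=PHARMACY_COLUMNS)
    hospital = pd.DataFrame(hosp_rows, columns=HOSPITAL_COLUMNS)
    outpatient = pd.DataFrame(outp_rows, columns=OUTPATIENT_COLUMNS)
    ground_truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)

    for df, name in [
        (demographics, "demographics"), (pharmacy, "pharmacy"),
        (hospital, "hospital"), (outpatient, "outpatient"),
        (ground_truth, "ground_truth"),
    ]:
        for col in _DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col])

    pharmacy.sort_values(
        ["patient_id", "dispensation_date", "atc_code"],
        inplace=True, ignore_index=True,
    )
    hospital.sort_values(
        ["patient_id", "admission_date", "drg_code"],
        inplace=True, ignore_index=True,
    )
    outpatient.sort_values(
        ["patient_id", "service_date", "service_type"],
        inplace=True, ignore_index=True,
    )
    return ClaimsTables(demographics, pharmacy, hospital, outpatient,
                        ground_truth)


# --- CSV round trip ---------------------------------------------------------


def write_tables(tables: ClaimsTables, directory) -> dict[str, Path]:
    """Write the five tables as CSV (ISO-8601 dates); returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in tables.table_names():
        df = getattr(tables, name).copy()
        for col in _DATE_COLUMNS[name]:
            df[col] = df[col].dt.strftime("%Y-%m-%d")
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_tables(directory) -> ClaimsTables:
    """Read tables previously written by :func:`write_tables`.

    The ``ground_truth.csv`` file is optional (real extractions have none).
    """
    directory = Path(directory)
    out = {}
    for name in TABLE_NAMES:
        path = directory / f"{name}.csv"
        if not path.exists():
            if name == "ground_truth":
                out[name] = pd.DataFrame(columns=GROUND_TRUTH_COLUMNS)
                continue
            raise FileNotFoundError(f"missing input table: {path}")
        dtypes = {c: "string" for c in _STR_COLUMNS[name]}
        df = pd.read_csv(path, dtype=dtypes)
        for col in _DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
        df[_STR_COLUMNS[name]] = df[_STR_COLUMNS[name]].astype(object)
        out[name] = df
    return ClaimsTables(**out)
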