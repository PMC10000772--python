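"""Cohort construction: screening, exclusions, index dating, labeling.

Implements the standard new-user / prevalent-user claims design for the TAF
cohort: adults with at least one ART dispensation in the inclusion window
are screened; patients with a single ART dispensation, an inter-dispensation
gap above one year, or a transfer out of the catchment area are excluded;
the index date is the first TAF-containing dispensation, prior-therapy
status (naive vs switcher) is judged on a 365-day look-back that is
half-open at the index (a dispensation on the index date itself never voids
naive status), and the baseline comorbidity profile plus a modified
Charlson index (HIV item weighted 0) are read from the look-back year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CohortSpec
from .synthetic_claims import ClaimsTables

logger = logging.getLogger(__name__)

AGE_CLASS_LABELS = ["<36", "36-55", ">55"]
AGE_CLASS_GLM_LABELS = ["<=50", "51-65", ">65"]


def _art_mask(atc: pd.Series, prefixes: tuple[str, ...]) -> pd.Series:
    return atc.str.startswith(tuple(prefixes))


def _normalize_icd(codes: pd.Series) -> pd.Series:
    return codes.str.replace(".", "", regex=False).str.strip()


def screen_art_patients(tables: ClaimsTables, spec: CohortSpec) -> set[str]:
    """Adults (>=18 y at first ART dispensation) with ART in the window."""
    ph = tables.pharmacy
    mask = _art_mask(ph["atc_code"], spec.art_atc_prefixes)
    mask &= ph["dispensation_date"] >= pd.Timestamp(spec.inclusion_start)
    mask &= ph["dispensation_date"] <= pd.Timestamp(spec.inclusion_end)
    art = ph.loc[mask, ["patient_id", "dispensation_date"]]
    if art.empty:
        return set()
    first_art = art.groupby("patient_id")["dispensation_date"].min()
    demo = tables.demographics.set_index("patient_id")
    joined = first_art.to_frame("first_art").join(demo[["birth_date"]])
    missing = joined["birth_date"].isna()
    if missing.any():
        for pid in joined.index[missing]:
            logger.warning("patient %s skipped: no birth date on record", pid)
        joined = joined[~missing]
    age_years = (joined["first_art"] - joined["birth_date"]).dt.days / 365.25
    return set(joined.index[age_years >= spec.min_age])


def apply_exclusions(
    candidates: set[str], tables: ClaimsTables, spec: CohortSpec
) -> tuple[set[str], pd.DataFrame]:
    """Drop single-dispensation, long-gap and transferred-out patients.

    Returns the retained IDs and a per-rule exclusion log (one row per
    excluded patient with the first rule that fired, in the order
    single_prescription, gap, transfer).
    """
    ph = tables.pharmacy
    art = ph[_art_mask(ph["atc_code"], spec.art_atc_prefixes)
             & ph["patient_id"].isin(candidates)]
    art = art.sort_values(["patient_id", "dispensation_date"])
    n_disp = art.groupby("patient_id")["dispensation_date"].nunique().to_dict()
    gaps = art.groupby("patient_id")["dispensation_date"].diff().dt.days
    max_gap = gaps.groupby(art["patient_id"]).max().fillna(0).to_dict()

    demo = tables.demographics.set_index("patient_id")
    transferred = set(
        demo.index[demo["transfer_out_date"].notna()]
    ) & candidates

    records = []
    kept = set()
    for pid in sorted(candidates):
        if n_disp.get(pid, 0) < 2:
            records.append((pid, "single_prescription"))
        elif max_gap.get(pid, 0) > spec.max_gap_days:
            records.append((pid, "gap"))
        elif pid in transferred:
            records.append((pid, "transfer"))
        else:
            kept.add(pid)
    log = pd.DataFrame(records, columns=["patient_id", "exclusion_rule"])
    return kept, log


def _age_classes(age: pd.Series) -> tuple[pd.Series, pd.Series]:
    tab = pd.cut(age, [-np.inf, 35, 55, np.inf],
                 labels=AGE_CLASS_LABELS, right=True)
    glm = pd.cut(age, [-np.inf, 50, 65, np.inf],
                 labels=AGE_CLASS_GLM_LABELS, right=True)
    return tab.astype(str), glm.astype(str)


def index_and_label(
    patient_ids: set[str], tables: ClaimsTables, spec: CohortSpec
) -> pd.DataFrame:
    """Build the TAF cohort frame: index date, regimen subtype, experience.

    Patients in ``patient_ids`` with no TAF dispensation inside the
    inclusion window are simply not part of the TAF cohort (they remain in
    the overall ART population).
    """
    ph = tables.pharmacy[tables.pharmacy["patient_id"].isin(patient_ids)]
    taf = ph[ph["atc_code"].isin(spec.taf_atc_codes)]
    taf = taf[
        (taf["dispensation_date"] >= pd.Timestamp(spec.inclusion_start))
        & (taf["dispensation_date"] <= pd.Timestamp(spec.inclusion_end))
    ]
    if taf.empty:
        return _empty_cohort()
    first = (
        taf.sort_values(["dispensation_date", "atc_code"])
        .groupby("patient_id")
        .first()
        .rename(columns={"dispensation_date": "index_date"})
    )

    demo = tables.demographics.set_index("patient_id")
    cohort = first[["index_date", "atc_code"]].join(
        demo[["sex", "birth_date", "enrollment_end", "death_date"]]
    )
    cohort["taf_subtype"] = np.where(
        cohort["atc_code"].isin(spec.str_atc_codes), "STR", "MTR"
    )

    # naive = no ART dispensation in [index - lookback, index)
    art = ph[_art_mask(ph["atc_code"], spec.art_atc_prefixes)]
    merged = art.merge(
        cohort["index_date"].rename("idx"), left_on="patient_id",
        right_index=True,
    )
    lb = merged["idx"] - pd.Timedelta(days=spec.lookback_days)
    prior = merged[
        (merged["dispensation_date"] >= lb)
        & (merged["dispensation_date"] < merged["idx"])
    ]
    has_prior = set(prior["patient_id"])
    cohort["experience"] = [
        "switcher" if pid in has_prior else "naive" for pid in cohort.index
    ]

    cohort["age_at_index"] = (
        (cohort["index_date"] - cohort["birth_date"]).dt.days / 365.25
    )
    cohort["age_class"], cohort["age_class_glm"] = _age_classes(
        cohort["age_at_index"]
    )
    # enrollment_end already reflects death/transfer truncation upstream
    cohort["followup_end"] = cohort["enrollment_end"]
    cohort["followup_days"] = (
        (cohort["followup_end"] - cohort["index_date"]).dt.days
    )
    cohort["died"] = cohort["death_date"].notna()
    short = (cohort["followup_days"] < spec.min_followup_days) & ~cohort["died"]
    if short.any():
        for pid in cohort.index[short]:
            logger.warning(
                "patient %s dropped: %d days of follow-up without death",
                pid, cohort.loc[pid, "followup_days"],
            )
        cohort = cohort[~short]
    cohort["inclusion_year"] = cohort["index_date"].dt.year

    cohort = cohort.drop(columns=["atc_code"]).reset_index()
    return cohort


def _empty_cohort() -> pd.DataFrame:
    cols = ["patient_id", "index_date", "sex", "birth_date",
            "enrollment_end", "death_date", "taf_subtype", "experience",
            "age_at_index", "age_class", "age_class_glm", "followup_end",
            "followup_days", "died", "inclusion_year"]
    return pd.DataFrame(columns=cols)


def characterize_baseline(
    cohort: pd.DataFrame, tables: ClaimsTables, spec: CohortSpec
) -> pd.DataFrame:
    """Flag baseline comorbidities and score the modified Charlson index.

    Evidence is any matching ATC (pharmacy) or ICD-9-CM (hospital discharge
    diagnosis) code in the half-open look-back window
    ``[index - lookback_days, index)``; events on or after the index date
    are ignored. The Charlson score is computed from look-back discharge
    diagnoses with the Deyo category table of ``spec.cci_categories``
    (hierarchical: e.g. metastatic disease supersedes non-metastatic
    malignancy) and the HIV item weighted 0.
    """
    if cohort.empty:
        out = cohort[["patient_id"]].copy()
        for cond in spec.comorbidity_code_map:
            out[cond] = pd.Series(dtype=bool)
        out["cci"] = pd.Series(dtype=int)
        return out
    idx = cohort.set_index("patient_id")["index_date"]

    ph = tables.pharmacy.merge(
        idx.rename("idx"), left_on="patient_id", right_index=True
    )
    ph = ph[
        (ph["dispensation_date"] >= ph["idx"] - pd.Timedelta(days=spec.lookback_days))
        & (ph["dispensation_date"] < ph["idx"])
    ]

    ho = tables.hospital.merge(
        idx.rename("idx"), left_on="patient_id", right_index=True
    )
    ho = ho[
        (ho["admission_date"] >= ho["idx"] - pd.Timedelta(days=spec.lookback_days))
        & (ho["admission_date"] < ho["idx"])
    ]
    icd_long = ho.assign(code=ho["icd9_codes"].str.split("|"))[
        ["patient_id", "code"]
    ].explode("code")
    icd_long = icd_long.dropna(subset=["code"])
    icd_long["code"] = _normalize_icd(icd_long["code"])

    out = cohort[["patient_id"]].copy()
    for cond, codes in spec.comorbidity_code_map.items():
        hit: set[str] = set()
        if codes.atc:
            m = ph["atc_code"].str.startswith(tuple(codes.atc))
            hit |= set(ph.loc[m, "patient_id"])
        if codes.icd9:
            m = icd_long["code"].str.startswith(tuple(codes.icd9))
            hit |= set(icd_long.loc[m, "patient_id"])
        out[cond] = out["patient_id"].isin(hit)

    cat_hits: dict[str, set[str]] = {}
    for cat, spec_cat in spec.cci_categories.items():
        m = icd_long["code"].str.startswith(tuple(spec_cat.icd9))
        cat_hits[cat] = set(icd_long.loc[m, "patient_id"])
    cci = {}
    for pid in out["patient_id"]:
        present = {c for c, ids in cat_hits.items() if pid in ids}
        for cat in list(present):
            for dominated in spec.cci_categories[cat].supersedes:
                present.discard(dominated)
        cci[pid] = sum(spec.cci_categories[c].weight for c in present)
    out["cci"] = out["patient_id"].map(cci).astype(int)
    return out


@dataclass
class CohortResult:
    """Output of the full screening funnel."""

    cohort: pd.DataFrame  # one row per TAF CohortPatient
    art_ids: set[str]  # the retained overall ART population
    n_screened: int
    exclusion_log: pd.DataFrame

    @property
    def attrition(self) -> dict[str, int]:
        counts = self.exclusion_log["exclusion_rule"].value_counts().to_dict()
        return {
            "screened": self.n_screened,
            **{f"excluded_{k}": int(v) for k, v in sorted(counts.items())},
            "art_retained": len(self.art_ids),
            "taf_cohort": len(self.cohort),
        }


def build_cohort(tables: ClaimsTables, spec: CohortSpec) -> CohortResult:
    """Run screening -> exclusions -> indexing -> characterization."""
    screened = screen_art_patients(tables, spec)
    kept, log = apply_exclusions(screened, tables, spec)
    cohort = index_and_label(kept, tables, spec)
    if not cohort.empty:
        baseline = characterize_baseline(cohort, tables, spec)
        cohort = cohort.merge(baseline, on="patient_id")
    cohort = cohort.sort_values("patient_id", ignore_index=True)
    return CohortResult(cohort, kept, len(screened), log)
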