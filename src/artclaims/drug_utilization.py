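"""Coverage timelines, PDC adherence and persistence classification.

The proportion of days covered (PDC) is computed from a union of half-open
day intervals built with carry-forward stockpiling: each dispensation
supplies ``n_packages * units_per_package`` days of therapy starting at the
dispensation date or at the end of the previous supply, whichever is later,
so early refills push coverage forward instead of being discarded. Day 0 is
the index date and all interval arithmetic is half-open.

Persistence, switch and discontinuation are judged on the last quarter of
the first follow-up year (days [274, 365) after index):

* discontinued - no ART dispensation in the window;
* persistent   - a TAF-class dispensation in the window;
* switched     - ART but no TAF in the window; the switch date is the first
  non-TAF ART dispensation after the last TAF dispensation.

Changes between TAF products (including MTR -> STR) are not switches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import CohortSpec
from .synthetic_claims import ClaimsTables

ADHERENCE_STRATA = ["<80", "81-95", ">95"]


def build_coverage(
    dispensation_days: Sequence[int],
    days_supplied: Sequence[int],
    window_days: int,
) -> list[tuple[int, int]]:
    """Carry-forward union of supply intervals, clipped to ``[0, window)``.

    Dispensations before day 0 are ignored. Returns sorted, disjoint,
    half-open ``(start, end)`` day intervals.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    order = np.argsort(dispensation_days, kind="stable")
    intervals: list[tuple[int, int]] = []
    carry_end = 0
    for k in order:
        day = int(dispensation_days[k])
        supply = int(days_supplied[k])
        if day < 0:
            continue
        start = max(day, carry_end)
        end = start + supply
        carry_end = end
        start, end = max(start, 0), min(end, window_days)
        if start >= window_days or end <= start:
            continue
        if intervals and start <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], end))
        else:
            intervals.append((start, end))
    return intervals


def covered_days(intervals: Sequence[tuple[int, int]]) -> int:
    return int(sum(e - s for s, e in intervals))


def compute_pdc(
    intervals: Sequence[tuple[int, int]], window_days: int
) -> float:
    """PDC = 100 * covered days / window days, capped at 100."""
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    return min(100.0, 100.0 * covered_days(intervals) / window_days)


@dataclass(frozen=True)
class AdherenceClass:
    adherent_95: bool
    adherent_85: bool
    stratum: str


def classify_adherence(pdc: float) -> AdherenceClass:
    """Threshold flags (strict ``>``) and the three-level stratum."""
    if not 0 <= pdc <= 100:
        raise ValueError(f"PDC {pdc} outside [0, 100]")
    if pdc > 95:
        stratum = ">95"
    elif pdc > 80:
        stratum = "81-95"
    else:
        stratum = "<80"
    return AdherenceClass(pdc > 95, pdc > 85, stratum)


@dataclass(frozen=True)
class StatusResult:
    persistent_taf: bool
    persistent_any_art: bool
    status: str  # persistent | switched | discontinued
    switch_day: Optional[int]
    censored: bool


def classify_status(
    taf_days: Sequence[int],
    other_art_days: Sequence[int],
    followup_days: int,
    *,
    rule: str = "date_in_window",
    quarter_basis: str = "first_year",
    days_supplied: int = 30,
) -> StatusResult:
    """Persistence / switch / discontinuation from post-index ART dates.

    ``taf_days``/``other_art_days`` are dispensation day offsets from index
    (pre-index entries are ignored). With follow-up shorter than a year the
    last quarter of the available follow-up is used and the result flagged
    censored. Under ``rule='coverage_in_window'`` a dispensation also counts
    if its supply interval overlaps the window.
    """
    taf = np.asarray([d for d in taf_days if d >= 0], dtype=int)
    other = np.asarray([d for d in other_art_days if d >= 0], dtype=int)

    if quarter_basis == "all_followup" or followup_days < 365:
        span = min(followup_days, 365) if quarter_basis == "first_year" else followup_days
        lo, hi = int(np.ceil(span * 3 / 4)), span
    else:
        lo, hi = 274, 365
    censored = followup_days < 365

    def in_window(days: np.ndarray) -> bool:
        if rule == "coverage_in_window":
            return bool(np.any((days < hi) & (days + days_supplied > lo)))
        return bool(np.any((days >= lo) & (days < hi)))

    persistent_taf = in_window(taf)
    persistent_any = persistent_taf or in_window(other)

    switch_day: Optional[int] = None
    if not persistent_any:
        status = "discontinued"
    elif persistent_taf:
        status = "persistent"
    else:
        status = "switched"
        last_taf = int(taf.max()) if taf.size else -1
        after = other[other > last_taf]
        if after.size:
            switch_day = int(after.min())
    return StatusResult(persistent_taf, persistent_any, status, switch_day,
                        censored)


def compute_utilization(
    cohort: pd.DataFrame,
    tables: ClaimsTables,
    spec: CohortSpec,
) -> pd.DataFrame:
    """Per-patient PDC, adherence flags and persistence status.

    PDC is measured on TAF-class coverage over a 365-day window from the
    index date (truncated at death for censored patients).
    """
    rows = []
    ph = tables.pharmacy.merge(
        cohort[["patient_id", "index_date"]], on="patient_id",
    )
    all_day = (ph["dispensation_date"] - ph["index_date"]).dt.days.to_numpy()
    all_art = ph["atc_code"].str.startswith(
        tuple(spec.art_atc_prefixes)).to_numpy()
    all_taf = ph["atc_code"].isin(spec.taf_atc_codes).to_numpy()
    all_supply = (ph["n_packages"] * ph["units_per_package"]).to_numpy()
    pids = ph["patient_id"].to_numpy()
    order = np.argsort(pids, kind="stable")
    uniq, starts = np.unique(pids[order], return_index=True)
    bounds = dict(zip(uniq, zip(starts, np.append(starts[1:], len(pids)))))
    empty_i = np.array([], dtype=int)

    for rec in cohort.itertuples(index=False):
        lohi = bounds.get(rec.patient_id)
        sel = order[lohi[0]:lohi[1]] if lohi is not None else empty_i
        window = int(min(365, rec.followup_days))
        day = all_day[sel]
        is_art = all_art[sel]
        is_taf = all_taf[sel]
        supply = all_supply[sel]

        taf_sel = is_taf & (day >= 0)
        intervals = build_coverage(day[taf_sel], supply[taf_sel], window)
        pdc = compute_pdc(intervals, window)
        adh = classify_adherence(pdc)
        st = classify_status(
            day[is_taf], day[is_art & ~is_taf], int(rec.followup_days),
            rule=spec.persistence_rule, quarter_basis=spec.quarter_basis,
            days_supplied=int(supply[taf_sel].max()) if taf_sel.any() else 30,
        )
        switch_date = (
            rec.index_date + pd.Timedelta(days=st.switch_day)
            if st.switch_day is not None else pd.NaT
        )
        rows.append((
            rec.patient_id, round(pdc, 4), adh.adherent_95, adh.adherent_85,
            adh.stratum, st.persistent_taf, st.persistent_any_art, st.status,
            switch_date, st.censored,
        ))
    return pd.DataFrame(rows, columns=[
        "patient_id", "pdc", "adherent_95", "adherent_85",
        "adherence_stratum", "persistent_taf", "persistent_any_art",
        "status", "switch_date", "censored",
    ])


def summarize_utilization(
    utilization: pd.DataFrame, cohort: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Cohort-level proportions (percent), overall and by subgroup."""
    if utilization.empty:
        return pd.DataFrame()
    df = utilization
    if cohort is not None:
        df = df.merge(
            cohort[["patient_id", "taf_subtype", "experience"]],
            on="patient_id", how="left",
        )

    def _one(sub: pd.DataFrame, label: str) -> dict:
        n = len(sub)
        return {
            "group": label,
            "n": n,
            "adherent_95_pct": 100 * sub["adherent_95"].mean(),
            "adherent_85_pct": 100 * sub["adherent_85"].mean(),
            "persistent_taf_pct": 100 * sub["persistent_taf"].mean(),
            "persistent_any_art_pct": 100 * sub["persistent_any_art"].mean(),
            "persistent_pct": 100 * (sub["status"] == "persistent").mean(),
            "switched_pct": 100 * (sub["status"] == "switched").mean(),
            "discontinued_pct": 100 * (sub["status"] == "discontinued").mean(),
        }

    out = [_one(df, "overall")]
    if cohort is not None:
        for col in ("taf_subtype", "experience"):
            for value, sub in df.groupby(col, observed=True):
                if len(sub):
                    out.append(_one(sub, str(value)))
    return pd.DataFrame(out)
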