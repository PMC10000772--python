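"""Annualized resource counts and direct-cost aggregation by cost item.

Five cost items are tracked from the payer's perspective: HIV-related drugs
(any ART dispensation), other drugs, HIV-related hospitalizations (DRG 488,
489, 490), other hospitalizations, and outpatient specialist services.
Money is handled internally in integer euro cents so the item costs sum to
the total exactly; annualized values divide by the person-years of the
analysis window. Patients who die before the end of a window are excluded
from that window (means are over alive patients), and total-cost outliers
above mean + 3 SD are removed in a single pass before any stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CohortSpec
from .synthetic_claims import ClaimsTables

logger = logging.getLogger(__name__)

COST_ITEMS = ["hiv_drugs", "other_drugs", "hiv_hosp", "other_hosp",
              "outpatient"]
COUNT_ITEMS = ["n_hiv_drug_disp", "n_other_drug_disp", "n_hiv_hosp",
               "n_other_hosp", "n_outpatient"]


def _to_cents(eur: pd.Series) -> np.ndarray:
    return np.round(eur.to_numpy(dtype=float) * 100).astype(np.int64)


def tally_resources(
    cohort: pd.DataFrame,
    tables: ClaimsTables,
    spec: CohortSpec,
    window: str = "first_year",
) -> pd.DataFrame:
    """Per-patient annualized counts and costs for one analysis window.

    ``window='first_year'`` uses the fixed 365-day interval after index and
    keeps only patients alive (and enrolled) through day 365;
    ``window='all_followup'`` uses ``[index, followup_end)`` with exact
    person-years (days / 365.25) and keeps patients alive at follow-up end.
    """
    if window not in {"first_year", "all_followup"}:
        raise ValueError(f"unknown window {window!r}")
    if cohort.empty:
        return pd.DataFrame(columns=["patient_id"])

    co = cohort.copy()
    if window == "first_year":
        co = co[co["followup_days"] >= 365]
        co["win_days"] = 365
    else:
        co = co[~co["died"].astype(bool)]
        co["win_days"] = co["followup_days"]
    co = co[co["win_days"] > 0]
    co["person_years"] = np.where(
        co["win_days"].eq(365) & (window == "first_year"),
        1.0, co["win_days"] / 365.25,
    )
    idx = co.set_index("patient_id")[["index_date", "win_days"]]

    def _window_events(df: pd.DataFrame, date_col: str) -> pd.DataFrame:
        m = df.merge(idx, left_on="patient_id", right_index=True)
        off = (m[date_col] - m["index_date"]).dt.days
        return m[(off >= 0) & (off < m["win_days"])].reset_index(drop=True)

    ph = _window_events(tables.pharmacy, "dispensation_date")
    is_art = ph["atc_code"].str.startswith(tuple(spec.art_atc_prefixes))
    ho = _window_events(tables.hospital, "admission_date")
    known = ho["drg_code"].isin(spec.hiv_drg_codes)
    is_hiv_drg = known  # unknown DRGs fall through to other-hospitalization
    op = _window_events(tables.outpatient, "service_date")

    out = co[["patient_id", "person_years", "win_days"]].copy()
    out = out.set_index("patient_id")

    def _agg(df: pd.DataFrame, cost_col: str) -> tuple[pd.Series, pd.Series]:
        counts = df.groupby("patient_id").size()
        cents = df.assign(_c=_to_cents(df[cost_col])).groupby("patient_id")["_c"].sum()
        return counts, cents

    pieces = {
        "hiv_drugs": _agg(ph[is_art], "cost_eur"),
        "other_drugs": _agg(ph[~is_art], "cost_eur"),
        "hiv_hosp": _agg(ho[is_hiv_drg], "tariff_eur"),
        "other_hosp": _agg(ho[~is_hiv_drg], "tariff_eur"),
        "outpatient": _agg(op, "tariff_eur"),
    }
    for (item, count_col) in zip(COST_ITEMS, COUNT_ITEMS):
        counts, cents = pieces[item]
        out[count_col] = counts.reindex(out.index).fillna(0).astype(int)
        out[f"{item}_cents"] = cents.reindex(out.index).fillna(0).astype(np.int64)
    out["total_cents"] = sum(out[f"{i}_cents"] for i in COST_ITEMS)

    py = out["person_years"]
    for count_col in COUNT_ITEMS:
        out[f"{count_col}_py"] = out[count_col] / py
    for item in COST_ITEMS:
        out[f"{item}_eur_py"] = out[f"{item}_cents"] / 100.0 / py
    out["total_eur_py"] = out["total_cents"] / 100.0 / py
    out["window"] = window
    return out.reset_index()


@dataclass
class OutlierResult:
    retained: pd.DataFrame
    excluded_ids: list[str]
    mean: float
    sd: float
    threshold: float


def exclude_outliers(
    breakdowns: pd.DataFrame, total_col: str = "total_eur_py"
) -> OutlierResult:
    """Single-pass mean + 3 SD trim on per-patient annualized total cost.

    Uses the sample SD (ddof=1); only patients strictly above the threshold
    are dropped, and the rule is not re-iterated on the trimmed sample.
    """
    totals = breakdowns[total_col].to_numpy(dtype=float)
    if len(totals) < 2:
        logger.warning("outlier rule skipped: fewer than 2 patients")
        return OutlierResult(breakdowns, [], float("nan"), float("nan"),
                             float("inf"))
    mean = float(np.mean(totals))
    sd = float(np.std(totals, ddof=1))
    threshold = mean + 3 * sd
    mask = totals > threshold
    excluded = breakdowns.loc[mask, "patient_id"].tolist()
    return OutlierResult(breakdowns.loc[~mask].copy(), excluded, mean, sd,
                         threshold)


def compare_cost_groups(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample comparison of per-patient totals -> (diff, p)."""
    from .stats_models import compare_groups

    res = compare_groups(a, b)
    return res.difference, res.p_value


def stratify_costs(
    breakdowns: pd.DataFrame,
    labels: pd.Series,
    compare: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-stratum n, mean and SD for each cost item (annualized EUR).

    ``labels`` maps patient_id -> stratum. If ``compare`` names two strata
    (or exactly two strata exist), a Welch comparison p-value per item is
    attached to every row. Empty strata are omitted with a log note.
    Outlier exclusion is the caller's responsibility and should run before
    stratification.
    """
    df = breakdowns.merge(
        labels.rename("stratum"), left_on="patient_id", right_index=True,
        how="left",
    )
    if df["stratum"].isna().any():
        raise ValueError("labels do not cover all retained patients")
    value_cols = [f"{i}_eur_py" for i in COST_ITEMS] + ["total_eur_py"]
    rows = []
    for stratum, sub in df.groupby("stratum", observed=True):
        if sub.empty:
            logger.info("stratum %s omitted: no patients", stratum)
            continue
        row = {"stratum": stratum, "n": len(sub)}
        for col in value_cols:
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sd"] = float(sub[col].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(row)
    table = pd.DataFrame(rows)

    strata = list(table["stratum"]) if not table.empty else []
    if compare is None and len(strata) == 2:
        compare = (strata[0], strata[1])
    if compare is not None and set(compare) <= set(strata):
        a = df[df["stratum"] == compare[0]]
        b = df[df["stratum"] == compare[1]]
        for col in value_cols:
            _, p = compare_cost_groups(a[col].to_numpy(), b[col].to_numpy())
            table[f"{col}_p"] = p
    return table


def plot_cost_bars(table: pd.DataFrame, path) -> None:
    """Stacked bar chart of mean annual cost by stratum (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    bottom = np.zeros(len(table))
    for item in COST_ITEMS:
        vals = table[f"{item}_eur_py_mean"].to_numpy()
        ax.bar(table["stratum"], vals, bottom=bottom, label=item)
        bottom += vals
    ax.set_ylabel("mean annual cost (EUR)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
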