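"""New-user cohort selection, index dates, episodes and follow-up windows.

Screening applies a fixed precedence of exclusion rules so that flow
counts are reproducible:

    prior ECT -> bipolar/schizophrenia dx -> CNS-disease dx -> age 18-64
    -> MDD dx during baseline -> multi-drug index

A patient with no qualifying index date (no antidepressant dispense in
the accrual window preceded by a 365-day drug-free washout) is recorded
with the ``washout_violation`` reason.  Follow-up runs from the index
date to the end of the first treatment episode or the study end,
whichever comes first; an episode ends once more than ``episode_gap_days``
antidepressant-free days elapse after the end of a supply run.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

from .canmat_rules import DrugCatalog

WASHOUT_DAYS = 365
EPISODE_GAP_DAYS = 120
AGE_MIN = 18
AGE_MAX = 64

MDD_PREFIXES = ("F32", "F33")
BIPOLAR_SCHIZO_PREFIXES = ("F20", "F30", "F31")
CNS_PREFIXES = tuple(f"F0{i}" for i in range(10))

EXCLUSION_REASONS = (
    "none",
    "prior_ect",
    "bipolar_or_schizo",
    "cns_disease",
    "age",
    "no_mdd_dx",
    "multi_drug_index",
    "washout_violation",
)


class CohortDataError(ValueError):
    pass


@dataclass(frozen=True)
class StudyWindow:
    accrual_start: pd.Timestamp
    accrual_end: pd.Timestamp
    study_end: pd.Timestamp

    @classmethod
    def default(cls) -> "StudyWindow":
        return cls(
            accrual_start=pd.Timestamp("2015-01-01"),
            accrual_end=pd.Timestamp("2017-12-31"),
            study_end=pd.Timestamp("2018-12-31"),
        )


def find_index(
    prescriptions: pd.DataFrame,
    window: StudyWindow,
    catalog: DrugCatalog,
    washout_days: int = WASHOUT_DAYS,
) -> tuple[pd.Timestamp, list[str]] | None:
    """First antidepressant dispense date in the accrual window with a clean
    washout, together with every AD drug dispensed on that date.

    Returns ``None`` when no date qualifies.
    """
    rx = prescriptions.copy()
    rx["dispense_date"] = pd.to_datetime(rx["dispense_date"])
    ad = rx[rx["drug_id"].map(lambda d: d in catalog and catalog.is_antidepressant(d))]
    if ad.empty:
        return None
    ad = ad.sort_values("dispense_date")
    dates = ad["dispense_date"].drop_duplicates()
    in_window = dates[(dates >= window.accrual_start) & (dates <= window.accrual_end)]
    all_dates = dates.to_numpy()
    for d in in_window:
        lo = d - pd.Timedelta(days=washout_days)
        if ((all_dates >= lo.to_datetime64()) & (all_dates < d.to_datetime64())).any():
            continue
        drugs = sorted(ad.loc[ad["dispense_date"] == d, "drug_id"].unique())
        return d, drugs
    return None


def build_episode(
    ad_dispenses: pd.DataFrame,
    index_date: pd.Timestamp,
    study_end: pd.Timestamp,
    gap_days: int = EPISODE_GAP_DAYS,
) -> pd.Timestamp:
    """End date of the treatment episode that starts at the index date.

    ``ad_dispenses`` needs dispense_date and days_supplied columns; the
    episode ends at the end of the supply run after which more than
    ``gap_days`` antidepressant-free days pass before the next dispense,
    capped at ``study_end``.
    """
    rx = ad_dispenses.copy()
    rx["dispense_date"] = pd.to_datetime(rx["dispense_date"])
    rx = rx[rx["dispense_date"] >= index_date].sort_values("dispense_date")
    if rx.empty:
        raise CohortDataError("no dispense on or after the index date")
    supply_end = index_date - pd.Timedelta(days=1)
    for row in rx.itertuples(index=False):
        d = row.dispense_date
        free_days = (d - supply_end).days - 1
        if free_days > gap_days:
            break
        end = d + pd.Timedelta(days=int(row.days_supplied) - 1)
        supply_end = max(supply_end, end)
    return min(supply_end, study_end)


def _age_at(birth_date: pd.Timestamp, on: pd.Timestamp) -> int:
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def _has_code(dx: pd.DataFrame, prefixes: tuple[str, ...], lo: pd.Timestamp, hi: pd.Timestamp) -> bool:
    if dx.empty:
        return False
    sel = dx[(dx["date"] >= lo) & (dx["date"] <= hi)]
    return sel["icd10_code"].str.upper().str.startswith(prefixes).any()


def screen_patients(
    tables: dict[str, pd.DataFrame],
    window: StudyWindow | None = None,
    catalog: DrugCatalog | None = None,
    *,
    washout_days: int = WASHOUT_DAYS,
    gap_days: int = EPISODE_GAP_DAYS,
    age_min: int = AGE_MIN,
    age_max: int = AGE_MAX,
) -> pd.DataFrame:
    """Screen every patient and emit one cohort row each.

    ``tables`` holds the five record tables (patients, prescriptions,
    diagnoses, visits, procedures).  The result carries index and
    follow-up fields for eligible patients and a single exclusion_reason
    for everyone screened.
    """
    if window is None:
        window = StudyWindow.default()
    if catalog is None:
        from .canmat_rules import load_catalog

        catalog = load_catalog()

    patients = tables["patients"].copy()
    for col in ("patient_id", "birth_date", "sex"):
        if col not in patients.columns:
            raise CohortDataError(f"patients table missing column {col!r}")
    patients["birth_date"] = pd.to_datetime(patients["birth_date"])

    rx = tables["prescriptions"].copy()
    rx["dispense_date"] = pd.to_datetime(rx["dispense_date"])
    dx = tables["diagnoses"].copy()
    if not dx.empty:
        dx["date"] = pd.to_datetime(dx["date"])
    procs = tables.get("procedures", pd.DataFrame(columns=["patient_id", "code", "date"])).copy()
    if not procs.empty:
        procs["date"] = pd.to_datetime(procs["date"])

    rx_by_pt = dict(list(rx.groupby("patient_id")))
    dx_by_pt = dict(list(dx.groupby("patient_id"))) if not dx.empty else {}
    proc_by_pt = dict(list(procs.groupby("patient_id"))) if not procs.empty else {}

    rows: list[dict] = []
    empty_dx = pd.DataFrame(columns=["patient_id", "icd10_code", "date"])
    for pt in patients.itertuples(index=False):
        pid = pt.patient_id
        if pd.isna(pt.birth_date) or pd.isna(pt.sex):
            raise CohortDataError(f"patient {pid!r} missing birth date or sex")
        prx = rx_by_pt.get(pid)
        row = {
            "patient_id": pid,
            "sex": pt.sex,
            "index_date": pd.NaT,
            "index_drug": "",
            "age_at_index": pd.NA,
            "index_setting": "",
            "episode_end": pd.NaT,
            "follow_up_end": pd.NaT,
            "exclusion_reason": "none",
        }
        found = None
        if prx is not None:
            found = find_index(prx, window, catalog, washout_days)
        if found is None:
            row["exclusion_reason"] = "washout_violation"
            rows.append(row)
            continue
        index_date, index_drugs = found
        pdx = dx_by_pt.get(pid, empty_dx)
        pproc = proc_by_pt.get(pid)
        baseline_lo = index_date - pd.Timedelta(days=washout_days)

        ad_rx = prx[
            prx["drug_id"].map(lambda d: d in catalog and catalog.is_antidepressant(d))
        ]
        episode_end = build_episode(ad_rx, index_date, window.study_end, gap_days)
        follow_up_end = min(episode_end, window.study_end)
        age = _age_at(pt.birth_date, index_date)

        setting = "outpatient"
        if prx is not None and "setting" in prx.columns:
            on_index = prx.loc[prx["dispense_date"] == index_date, "setting"]
            if (on_index == "inpatient").any():
                setting = "inpatient"

        reason = "none"
        if pproc is not None and (
            (pproc["code"].str.upper() == "ECT") & (pproc["date"] < index_date)
        ).any():
            reason = "prior_ect"
        elif _has_code(pdx, BIPOLAR_SCHIZO_PREFIXES, baseline_lo, follow_up_end):
            reason = "bipolar_or_schizo"
        elif _has_code(pdx, CNS_PREFIXES, baseline_lo, follow_up_end):
            reason = "cns_disease"
        elif not (age_min <= age <= age_max):
            reason = "age"
        elif not _has_code(pdx, MDD_PREFIXES, baseline_lo, index_date):
            reason = "no_mdd_dx"
        elif len(index_drugs) >= 2:
            reason = "multi_drug_index"

        row.update(
            index_date=index_date,
            index_drug="+".join(index_drugs),
            age_at_index=age,
            index_setting=setting,
            episode_end=episode_end,
            follow_up_end=follow_up_end,
            exclusion_reason=reason,
        )
        rows.append(row)
    cohort = pd.DataFrame(rows)
    return cohort


def exclusion_flow(cohort: pd.DataFrame) -> pd.DataFrame:
    """Tabulate screened patients by exclusion reason (eligible = none)."""
    counts = cohort["exclusion_reason"].value_counts()
    rows = [
        {"reason": r, "n": int(counts.get(r, 0))}
        for r in EXCLUSION_REASONS
    ]
    rows.append({"reason": "screened_total", "n": int(len(cohort))})
    return pd.DataFrame(rows)
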