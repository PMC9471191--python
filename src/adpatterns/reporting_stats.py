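"""Summary tables, yearly trend tests, discordance flow and utilization.

Percentages are always recomputed from their numerator/denominator pair;
the Cochran-Armitage trend statistic uses the standard score form

    T = sum_i s_i (x_i - n_i p),   Var(T) = p (1 - p) (sum n_i s_i^2
                                            - (sum n_i s_i)^2 / N)

with a two-sided normal p-value and no continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class TrendTestResult:
    Z: float
    p: float
    scores: tuple[float, ...]
    counts: tuple[int, ...]
    totals: tuple[int, ...]

    @property
    def abs_Z(self) -> float:
        return abs(self.Z)


@dataclass(frozen=True)
class UtilizationSummary:
    n_patients: int
    person_years: float
    visits_per_person_year: float
    hospitalizations_per_person_year: float
    follow_up_median_q1_q3: tuple[float, float, float]
    visit_interval_median_q1_q3: tuple[float, float, float] | None
    hospital_stay_median_q1_q3: tuple[float, float, float] | None


def cochran_armitage(
    counts: Sequence[int],
    totals: Sequence[int],
    scores: Sequence[float] | None = None,
    continuity_correction: bool = False,
) -> TrendTestResult:
    """Trend in binomial proportions across ordered groups.

    ``counts`` are successes per group, ``totals`` the denominators;
    default scores 1..k.  Z is signed by the direction of the trend under
    ascending scores.
    """
    x = np.asarray(counts, dtype=float)
    n = np.asarray(totals, dtype=float)
    if len(x) != len(n) or len(x) < 2:
        raise ValueError("need counts and totals for at least two ordered groups")
    if ((x < 0) | (x > n)).any():
        raise ValueError("counts must satisfy 0 <= count <= total per group")
    s = np.arange(1, len(x) + 1, dtype=float) if scores is None else np.asarray(scores, float)
    N = n.sum()
    pbar = x.sum() / N
    if pbar in (0.0, 1.0):
        raise ValueError("trend statistic undefined for an all-success or all-failure table")
    T = float((s * (x - n * pbar)).sum())
    var = pbar * (1 - pbar) * ((n * s**2).sum() - (n * s).sum() ** 2 / N)
    if continuity_correction:
        T = np.sign(T) * max(0.0, abs(T) - 0.5)
    Z = T / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(Z))
    return TrendTestResult(
        Z=float(Z),
        p=float(p),
        scores=tuple(float(v) for v in s),
        counts=tuple(int(v) for v in x),
        totals=tuple(int(v) for v in n),
    )


def percent(numerator: int, denominator: int) -> float:
    if denominator == 0:
        return float("nan")
    return 100.0 * numerator / denominator


def proportion_table(
    concordance: pd.DataFrame,
    cohort: pd.DataFrame,
    by_year: bool = True,
) -> pd.DataFrame:
    """Concordance-proportion rows for three families of denominators.

    * overall — concordant over all eligible patients;
    * first_line — level-1 concordant over all eligible patients;
    * optimized — overall concordant among patients with a medication
      change after a concordant level 1 (first-line initiators who moved
      beyond level 1).
    """
    eligible = cohort[cohort["exclusion_reason"] == "none"][["patient_id", "index_date"]]
    df = concordance.merge(eligible, on="patient_id", how="inner")
    df["index_year"] = pd.to_datetime(df["index_date"]).dt.year
    df["first_line"] = (df["level1_flag"] == "concordant").astype(int)
    df["optimized_after_first_line"] = ((df["first_line"] == 1) & (df["optimized"] == 1)).astype(int)

    rows: list[dict] = []

    def emit(family: str, stratum, num: int, den: int) -> None:
        rows.append(
            {
                "family": family,
                "stratum": stratum,
                "n": num,
                "denominator": den,
                "percent": round(percent(num, den), 2) if den else float("nan"),
            }
        )

    strata: list[tuple[str, pd.DataFrame]] = [("all", df)]
    if by_year:
        strata += [(str(y), sub) for y, sub in df.groupby("index_year")]
    for label, sub in strata:
        emit("overall", label, int(sub["overall"].sum()), len(sub))
        emit("first_line", label, int(sub["first_line"].sum()), len(sub))
        opt = sub[sub["optimized_after_first_line"] == 1]
        emit("optimized", label, int(opt["overall"].sum()), len(opt))
    return pd.DataFrame(rows, columns=["family", "stratum", "n", "denominator", "percent"])


def proportion_from_counts(pairs: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Run the proportion computation on printed (numerator, denominator)
    contingency pairs; a worked-example entry point."""
    rows = [
        {
            "family": label,
            "stratum": "all",
            "n": num,
            "denominator": den,
            "percent": round(percent(num, den), 2),
        }
        for label, (num, den) in pairs.items()
    ]
    return pd.DataFrame(rows, columns=["family", "stratum", "n", "denominator", "percent"])


def duration_table(levels: pd.DataFrame, max_level: int = 3) -> pd.DataFrame:
    """Per-level duration summaries split by whether the level was final.

    Subgroups: for level 1, patients who stayed on the index regimen vs
    those with a later medication change; for higher levels, stopped
    there vs changed again; plus the total.
    """
    from .pattern_engine import DURATION_BINS

    lv = levels.copy()
    max_per_pt = lv.groupby("patient_id")["level_index"].transform("max")
    lv["is_final"] = lv["level_index"] == max_per_pt

    rows = []
    for level in range(1, max_level + 1):
        sub = lv[lv["level_index"] == level]
        if sub.empty:
            continue
        groups = {
            "stopped_here": sub[sub["is_final"]],
            "changed_again": sub[~sub["is_final"]],
            "total": sub,
        }
        for name, g in groups.items():
            if g.empty:
                continue
            d = g["duration_days"]
            row = {
                "level": level,
                "subgroup": name,
                "n": len(g),
                "mean": round(float(d.mean()), 2),
                "sd": round(float(d.std(ddof=1)), 2) if len(g) > 1 else 0.0,
                "median": float(d.median()),
                "q1": float(d.quantile(0.25)),
                "q3": float(d.quantile(0.75)),
            }
            binned = g["duration_bin"].value_counts()
            for b in DURATION_BINS:
                row[f"pct_{b}"] = round(percent(int(binned.get(b, 0)), len(g)), 2)
            rows.append(row)
    return pd.DataFrame(rows)


def pattern_table(
    transitions: pd.DataFrame,
    cohort: pd.DataFrame,
    top_n: int = 3,
) -> pd.DataFrame:
    """First-change kinds, top drugs per pattern and subsequent patterns.

    Percent denominators follow the tabulation rules: first-change rows
    use the eligible cohort size; subsequent-pattern rows (1a-1c switch
    branch, 2a-2c add-on branch) use the count of that branch's first
    change; top-drug rows likewise.
    """
    n_cohort = int((cohort["exclusion_reason"] == "none").sum())
    tr = transitions.sort_values(["patient_id", "event_index"])
    real = tr[tr["kind"] != "attempt"]
    first = real.groupby("patient_id").head(1)
    second = real.groupby("patient_id").nth(1)

    attempt_only = set(tr.loc[tr["kind"] == "attempt", "patient_id"]) - set(
        real["patient_id"]
    )

    rows: list[dict] = []

    def emit(item: str, n: int, den: int) -> None:
        rows.append(
            {"item": item, "n": n, "denominator": den, "percent": round(percent(n, den), 2)}
        )

    emit("cohort", n_cohort, n_cohort)
    changers = first["patient_id"].nunique()
    emit("any_change", changers, n_cohort)
    pattern_codes = {"switch": ("1", "switch"), "add_on": ("2", "add_on")}
    for kind, (code, label) in pattern_codes.items():
        f = first[first["kind"] == kind]
        emit(f"first_{label}", len(f), n_cohort)
        drugs = f["new_drugs"].str.split("+").explode()
        for drug, cnt in drugs.value_counts().head(top_n).items():
            emit(f"first_{label}_drug_{drug}", int(cnt), len(f))
        ids = set(f["patient_id"])
        nxt = second[second["patient_id"].isin(ids)]
        n_sw = int((nxt["kind"] == "switch").sum())
        n_ad = int((nxt["kind"] == "add_on").sum())
        emit(f"pattern_{code}a_{label}_unchanged", len(f) - n_sw - n_ad, len(f))
        emit(f"pattern_{code}b_{label}_switch", n_sw, len(f))
        emit(f"pattern_{code}c_{label}_addon", n_ad, len(f))
    emit("attempt_only", len(attempt_only), n_cohort)
    return pd.DataFrame(rows, columns=["item", "n", "denominator", "percent"])


def discordance_flow(
    concordance: pd.DataFrame,
    transitions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Flow from first-line initiators through optimized treatment to
    strategy-specific discordance, with multi-drug breakdowns.

    Works from the concordance table alone: the first transition kind and
    multi-drug flag are carried on it.
    """
    first_line = concordance[concordance["level1_flag"] == "concordant"]
    optimized = first_line[
        (first_line["optimized"] == 1) & (first_line["first_transition_kind"] != "")
    ]
    rows: list[dict] = []

    def emit(item: str, n: int, den: int) -> None:
        rows.append(
            {"item": item, "n": n, "denominator": den, "percent": round(percent(n, den), 2)}
        )

    emit("first_line_initiators", len(first_line), len(concordance))
    emit("optimized_after_first_line", len(optimized), len(first_line))
    for kind, label in (("switch", "switch"), ("add_on", "add_on")):
        grp = optimized[optimized["first_transition_kind"] == kind]
        level2_flag = grp["level2_flag"]
        disc = grp[level2_flag == "discordant"]
        emit(f"{label}_strategy", len(grp), len(optimized))
        emit(f"{label}_discordant", len(disc), len(grp))
        emit(f"{label}_discordant_multi", int((disc["first_transition_multi"] == 1).sum()), len(grp))
    return pd.DataFrame(rows, columns=["item", "n", "denominator", "percent"])


def discordance_flow_from_counts(counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Flow percentages recomputed from printed (numerator, denominator)
    pairs; same output layout as :func:`discordance_flow`."""
    rows = [
        {"item": item, "n": n, "denominator": den, "percent": round(percent(n, den), 2)}
        for item, (n, den) in counts.items()
    ]
    return pd.DataFrame(rows, columns=["item", "n", "denominator", "percent"])


def _mq(series: pd.Series) -> tuple[float, float, float] | None:
    if series.empty:
        return None
    return (
        float(series.median()),
        float(series.quantile(0.25)),
        float(series.quantile(0.75)),
    )


def utilization_summary(
    cohort: pd.DataFrame,
    visits: pd.DataFrame,
    patient_ids: Sequence[str] | None = None,
) -> UtilizationSummary:
    """Visit and hospitalization rates per person-year for a patient set.

    Visits count distinct visit dates per patient inside the follow-up
    window; person-years use 365.25-day years.
    """
    sub = cohort[cohort["exclusion_reason"] == "none"].copy()
    if patient_ids is not None:
        sub = sub[sub["patient_id"].isin(set(patient_ids))]
    sub["index_date"] = pd.to_datetime(sub["index_date"])
    sub["follow_up_end"] = pd.to_datetime(sub["follow_up_end"])
    sub["fu_days"] = (sub["follow_up_end"] - sub["index_date"]).dt.days + 1
    person_years = float(sub["fu_days"].sum()) / DAYS_PER_YEAR

    v = visits[visits["patient_id"].isin(set(sub["patient_id"]))].copy()
    if not v.empty:
        v["date"] = pd.to_datetime(v["date"])
        windows = sub.set_index("patient_id")[["index_date", "follow_up_end"]]
        v = v.join(windows, on="patient_id", how="inner")
        v = v[(v["date"] >= v["index_date"]) & (v["date"] <= v["follow_up_end"])]
    n_visits = (
        int(v.groupby("patient_id")["date"].nunique().sum()) if not v.empty else 0
    )

    hosp = v[v["setting"] == "inpatient"] if not v.empty else v
    n_hosp = len(hosp)
    stays = pd.Series(dtype=float)
    if n_hosp and "admission_date" in hosp.columns:
        adm = pd.to_datetime(hosp["admission_date"], errors="coerce")
        dis = pd.to_datetime(hosp["discharge_date"], errors="coerce")
        stays = (dis - adm).dt.days.dropna().astype(float)

    intervals = pd.Series(dtype=float)
    if not v.empty:
        per_pt = v.sort_values("date").groupby("patient_id")["date"]
        diffs = per_pt.diff().dt.days.dropna()
        if not diffs.empty:
            intervals = diffs.astype(float)

    return UtilizationSummary(
        n_patients=len(sub),
        person_years=person_years,
        visits_per_person_year=(n_visits / person_years) if person_years > 0 else float("nan"),
        hospitalizations_per_person_year=(
            n_hosp / person_years if person_years > 0 else float("nan")
        ),
        follow_up_median_q1_q3=_mq(sub["fu_days"].astype(float)) or (0.0, 0.0, 0.0),
        visit_interval_median_q1_q3=_mq(intervals),
        hospital_stay_median_q1_q3=_mq(stays),
    )
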