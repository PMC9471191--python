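"""Synthetic patient-level EMR tables with per-patient ground truth.

Emits five delimited record tables — patients, prescriptions, diagnoses,
visits, procedures — shaped like a hospital EMR export, plus a ground
truth object per patient that downstream stages never read.

Two generation modes:

* ``clean`` — prescriptions realize each patient's intended level
  sequence exactly (abutting refills, no jitter), so the pattern engine
  must recover the intended levels verbatim; used for round-trip tests.
* ``noisy`` — adds refill gaps inside the grace period, start-date
  jitter, extra short attempts and occasional post-episode re-dispenses;
  ground truth is indicative only.

All dates are day-granular ISO-8601 strings; a fixed seed reproduces the
tables byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import canmat_rules
from .canmat_rules import CanmatTierTable, DrugCatalog

TABLE_NAMES = ("patients", "prescriptions", "diagnoses", "visits", "procedures")

FIXTURE_NAMES = (
    "addon_35d_overlap",
    "switch_20d_overlap",
    "attempt_15d_supply",
    "grace_gap_10d",
    "multi_switch_2drugs",
    "washout_violation",
    "episode_gap_130d",
)

_MDD_CODES = ("F32.0", "F32.1", "F32.2", "F32.9", "F33.0", "F33.1", "F33.2")
_EXCLUDED_DX_CODE = {"bipolar_or_schizo": ("F31.1", "F30.1", "F20.0"), "cns_disease": ("F06.7", "F03", "F07.0")}


class SimConfigError(ValueError):
    pass


def _default_age_distribution() -> dict[str, float]:
    # Age-group shares shaped like the study population.
    return {"18-30": 0.3989, "31-40": 0.2619, "41-50": 0.1434, "51-65": 0.1958}


def _default_index_drug_weights() -> dict[str, float]:
    return {
        "escitalopram": 0.2937,
        "sertraline": 0.1791,
        "mirtazapine": 0.1026,
        "venlafaxine": 0.1011,
        "paroxetine": 0.0883,
        "fluoxetine": 0.05,
        "duloxetine": 0.04,
        "citalopram": 0.03,
        "fluvoxamine": 0.025,
        "agomelatine": 0.02,
        "bupropion": 0.015,
        "milnacipran": 0.01,
        "trazodone": 0.02,
        "amitriptyline": 0.01,
        "clomipramine": 0.007,
        "reboxetine": 0.005,
        "maprotiline": 0.0032,
    }


def _default_switch_drug_weights() -> dict[str, float]:
    return {
        "escitalopram": 0.25,
        "venlafaxine": 0.20,
        "mirtazapine": 0.14,
        "sertraline": 0.10,
        "duloxetine": 0.08,
        "fluoxetine": 0.06,
        "paroxetine": 0.06,
        "trazodone": 0.04,
        "amitriptyline": 0.04,
        "reboxetine": 0.02,
        "maprotiline": 0.01,
    }


def _default_addon_drug_weights() -> dict[str, float]:
    return {
        "mirtazapine": 0.23,
        "quetiapine": 0.16,
        "trazodone": 0.14,
        "olanzapine": 0.08,
        "aripiprazole": 0.08,
        "lithium": 0.06,
        "buspirone": 0.07,
        "valproate": 0.05,
        "fluoxetine": 0.05,
        "sertraline": 0.04,
        "bupropion": 0.04,
    }


def _default_level_duration_model() -> dict[int, tuple[float, float]]:
    # (median days, log-scale sigma) per level, shaped like the study's
    # duration table.
    return {1: (28.0, 1.2), 2: (64.5, 0.94), 3: (70.5, 0.95)}


@dataclass
class SimConfig:
    """All knobs of the generator; defaults mirror the study's headline rates."""

    n_patients: int = 1000
    seed: int = 0
    mode: str = "clean"
    accrual_start: str = "2015-01-01"
    accrual_end: str = "2017-12-31"
    study_end: str = "2018-12-31"
    age_distribution: dict[str, float] = field(default_factory=_default_age_distribution)
    female_fraction: float = 0.6625
    index_drug_weights: dict[str, float] = field(default_factory=_default_index_drug_weights)
    p_multi_drug_index: float = 0.02
    p_excluded_dx: dict[str, float] = field(
        default_factory=lambda: {"bipolar_or_schizo": 0.015, "cns_disease": 0.005}
    )
    p_prior_ect: float = 0.002
    p_no_mdd_dx: float = 0.01
    p_age_violation: float = 0.01
    p_washout_violation: float = 0.01
    p_inpatient_index: float = 0.0047
    p_change: float = 0.1557
    p_switch_given_change: float = 0.5423
    p_second_change: float = 0.4713
    p_switch_given_second_change: float = 0.8470
    p_multi_switch: float = 0.2349
    p_multi_addon: float = 0.0438
    p_attempt: float = 0.0077
    switch_drug_weights: dict[str, float] = field(default_factory=_default_switch_drug_weights)
    addon_drug_weights: dict[str, float] = field(default_factory=_default_addon_drug_weights)
    level_duration_model: dict[int, tuple[float, float]] = field(
        default_factory=_default_level_duration_model
    )
    refill_days: int = 28
    visit_interval_model: tuple[float, float] = (4.0, 7.0)  # gamma shape, scale
    dropout_model: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise SimConfigError("n_patients must be non-negative")
        if self.mode not in {"clean", "noisy"}:
            raise SimConfigError(f"mode must be clean or noisy, got {self.mode!r}")
        probs = {
            "female_fraction": self.female_fraction,
            "p_multi_drug_index": self.p_multi_drug_index,
            "p_prior_ect": self.p_prior_ect,
            "p_no_mdd_dx": self.p_no_mdd_dx,
            "p_age_violation": self.p_age_violation,
            "p_washout_violation": self.p_washout_violation,
            "p_inpatient_index": self.p_inpatient_index,
            "p_change": self.p_change,
            "p_switch_given_change": self.p_switch_given_change,
            "p_second_change": self.p_second_change,
            "p_switch_given_second_change": self.p_switch_given_second_change,
            "p_multi_switch": self.p_multi_switch,
            "p_multi_addon": self.p_multi_addon,
            "p_attempt": self.p_attempt,
            **{f"p_excluded_dx[{k}]": v for k, v in self.p_excluded_dx.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {p}")
        for name, weights in (
            ("age_distribution", self.age_distribution),
            ("index_drug_weights", self.index_drug_weights),
            ("switch_drug_weights", self.switch_drug_weights),
            ("addon_drug_weights", self.addon_drug_weights),
        ):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise SimConfigError(f"{name} weights sum to {total}, expected 1")
        start = pd.Timestamp(self.accrual_start)
        end = pd.Timestamp(self.accrual_end)
        study_end = pd.Timestamp(self.study_end)
        if not (start <= end <= study_end):
            raise SimConfigError("accrual_window must lie within the study period")
        if self.refill_days < 1:
            raise SimConfigError("refill_days must be positive")


@dataclass
class GroundTruth:
    """Oracle labels for one simulated patient (never read by the pipeline)."""

    patient_id: str
    eligible: bool
    exclusion_reason: str
    intended_levels: list[tuple[frozenset[str], str, int]]
    intended_concordant: bool | None


_AGE_RANGE = {"18-30": (18, 30), "31-40": (31, 40), "41-50": (41, 50), "51-65": (51, 64)}


class _Recorder:
    """Accumulates record rows for all patients."""

    def __init__(self) -> None:
        self.patients: list[dict] = []
        self.rx: list[dict] = []
        self.dx: list[dict] = []
        self.visits: list[dict] = []
        self.procs: list[dict] = []

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "patients": pd.DataFrame(
                self.patients, columns=["patient_id", "birth_date", "sex"]
            ),
            "prescriptions": pd.DataFrame(
                self.rx,
                columns=["patient_id", "drug_id", "dispense_date", "days_supplied", "setting"],
            ),
            "diagnoses": pd.DataFrame(self.dx, columns=["patient_id", "icd10_code", "date"]),
            "visits": pd.DataFrame(
                self.visits,
                columns=["patient_id", "date", "setting", "admission_date", "discharge_date"],
            ),
            "procedures": pd.DataFrame(self.procs, columns=["patient_id", "code", "date"]),
        }


def _iso(ts: pd.Timestamp) -> str:
    return ts.date().isoformat()


def _sample_weighted(rng: np.random.Generator, weights: dict[str, float]) -> str:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _lognormal_days(rng: np.random.Generator, median: float, sigma: float) -> int:
    return max(1, int(round(float(rng.lognormal(math.log(median), sigma)))))


def _sample_duration(
    rng: np.random.Generator,
    model: dict[int, tuple[float, float]],
    level: int,
    minimum: int,
    cap: int,
) -> int:
    median, sigma = model[min(level, max(model))]
    for _ in range(200):
        d = _lognormal_days(rng, median, sigma)
        if minimum <= d <= cap:
            return d
    return max(minimum, min(cap, int(median)))


def generate_population(
    config: SimConfig,
    tiers: CanmatTierTable | None = None,
    catalog: DrugCatalog | None = None,
) -> tuple[dict[str, pd.DataFrame], list[GroundTruth]]:
    """Simulate the record tables and ground truth for one population."""
    if tiers is None:
        tiers = canmat_rules.load_tier_table()
    if catalog is None:
        catalog = canmat_rules.load_catalog()
    rng = np.random.default_rng(config.seed)
    rec = _Recorder()
    truths: list[GroundTruth] = []

    accrual_start = pd.Timestamp(config.accrual_start)
    accrual_end = pd.Timestamp(config.accrual_end)
    study_end = pd.Timestamp(config.study_end)
    accrual_days = (accrual_end - accrual_start).days

    exclusion_kinds = [
        ("prior_ect", config.p_prior_ect),
        *[(k, v) for k, v in config.p_excluded_dx.items()],
        ("age", config.p_age_violation),
        ("no_mdd_dx", config.p_no_mdd_dx),
        ("multi_drug_index", config.p_multi_drug_index),
        ("washout_violation", config.p_washout_violation),
    ]

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        sex = "F" if rng.random() < config.female_fraction else "M"

        exclusion = "none"
        u = rng.random()
        acc = 0.0
        for kind, p in exclusion_kinds:
            acc += p
            if u < acc:
                exclusion = kind
                break

        index_date = accrual_start + pd.Timedelta(days=int(rng.integers(0, accrual_days + 1)))
        if exclusion == "washout_violation":
            # Prior AD dispense just before the accrual window, index within
            # the 365-day washout of it, and no later qualifying dispense.
            offset = int(rng.integers(1, 61))
            prior_date = accrual_start - pd.Timedelta(days=offset)
            v = int(rng.integers(max(offset, 30), 365))
            index_date = prior_date + pd.Timedelta(days=v)

        if exclusion == "age":
            age = int(rng.choice([16, 17, 65, 70, 75]))
        else:
            bin_label = _sample_weighted(rng, config.age_distribution)
            lo, hi = _AGE_RANGE.get(bin_label, (18, 64))
            age = int(rng.integers(lo, hi + 1))
        birth_date = (
            index_date
            - pd.DateOffset(years=age)
            - pd.Timedelta(days=int(rng.integers(0, 365)))
        )
        rec.patients.append(
            {"patient_id": pid, "birth_date": _iso(pd.Timestamp(birth_date)), "sex": sex}
        )

        # Diagnoses: MDD at index unless the violation is its absence.
        if exclusion != "no_mdd_dx":
            rec.dx.append(
                {
                    "patient_id": pid,
                    "icd10_code": str(rng.choice(_MDD_CODES)),
                    "date": _iso(index_date),
                }
            )
        else:
            rec.dx.append({"patient_id": pid, "icd10_code": "F41.1", "date": _iso(index_date)})

        setting = "inpatient" if rng.random() < config.p_inpatient_index else "outpatient"

        # Treatment plan ------------------------------------------------
        available = (study_end - index_date).days + 1
        used: set[str] = set()
        index_drug = _sample_weighted(rng, config.index_drug_weights)
        used.add(index_drug)
        index_drugs = [index_drug]
        if exclusion == "multi_drug_index":
            second = _pick_drug(rng, config.index_drug_weights, used)
            index_drugs.append(second)
            used.add(second)

        if exclusion == "none":
            changed = rng.random() < config.p_change
        else:
            changed = False
        n_levels = 1
        entries: list[str] = ["initial"]
        if changed:
            n_levels = 3 if rng.random() < config.p_second_change else 2
            entries.append(
                "switch" if rng.random() < config.p_switch_given_change else "add_on"
            )
            if n_levels == 3:
                entries.append(
                    "switch"
                    if rng.random() < config.p_switch_given_second_change
                    else "add_on"
                )

        regimens: list[frozenset[str]] = [frozenset(index_drugs)]
        for li in range(1, n_levels):
            entry = entries[li]
            p_multi = config.p_multi_switch if entry == "switch" else config.p_multi_addon
            n_new = 2 if rng.random() < p_multi else 1
            weights = (
                config.switch_drug_weights if entry == "switch" else config.addon_drug_weights
            )
            new = set()
            while len(new) < n_new:
                new.add(_pick_drug(rng, weights, used | new))
            used |= new
            prev = regimens[-1]
            regimens.append(frozenset(new) if entry == "switch" else prev | frozenset(new))

        durations: list[int] = []
        budget = available
        for li in range(n_levels):
            later = n_levels - li - 1
            minimum = 1 if li == 0 else 30
            cap = max(minimum, budget - 37 * later)
            d = _sample_duration(rng, config.level_duration_model, li + 1, minimum, cap)
            durations.append(d)
            budget -= d

        # Realize prescriptions ----------------------------------------
        noisy = config.mode == "noisy"
        level_starts = [0]
        for d in durations[:-1]:
            level_starts.append(level_starts[-1] + d)
        treat_end = level_starts[-1] + durations[-1] - 1

        # Span of membership per drug (day offsets relative to index).
        spans: dict[str, tuple[int, int]] = {}
        for li, reg in enumerate(regimens):
            lv_start = level_starts[li]
            lv_end = level_starts[li] + durations[li] - 1
            for drug in reg:
                if drug in spans:
                    spans[drug] = (spans[drug][0], lv_end)
                else:
                    spans[drug] = (lv_start, lv_end)

        for drug, (s, e) in spans.items():
            _emit_refills(rec, rng, pid, drug, index_date, s, e, config.refill_days, setting, noisy)

        # Attempts: a short extra drug that never changes the level.
        p_attempt = config.p_attempt if not noisy else max(config.p_attempt, 0.08)
        if exclusion == "none" and rng.random() < p_attempt:
            li = int(rng.integers(0, n_levels))
            lv_start, dur = level_starts[li], durations[li]
            if dur >= 9:
                off = int(rng.integers(1, dur - 7))
                supply = int(min(21, dur - off, 7 + rng.integers(0, 15)))
                if supply >= 1:
                    pool = [d for d in config.switch_drug_weights if d not in used]
                    if pool:
                        adrug = str(rng.choice(pool))
                        used.add(adrug)
                        rec.rx.append(
                            {
                                "patient_id": pid,
                                "drug_id": adrug,
                                "dispense_date": _iso(index_date + pd.Timedelta(days=lv_start + off)),
                                "days_supplied": supply,
                                "setting": setting,
                            }
                        )

        if exclusion == "washout_violation":
            rec.rx.append(
                {
                    "patient_id": pid,
                    "drug_id": index_drug,
                    "dispense_date": _iso(prior_date),
                    "days_supplied": config.refill_days,
                    "setting": "outpatient",
                }
            )
        if exclusion == "prior_ect":
            rec.procs.append(
                {
                    "patient_id": pid,
                    "code": "ECT",
                    "date": _iso(index_date - pd.Timedelta(days=int(rng.integers(30, 301)))),
                }
            )
        if exclusion in _EXCLUDED_DX_CODE:
            code = str(rng.choice(_EXCLUDED_DX_CODE[exclusion]))
            when = index_date + pd.Timedelta(days=int(rng.integers(0, max(1, treat_end))))
            rec.dx.append({"patient_id": pid, "icd10_code": code, "date": _iso(when)})

        if noisy and exclusion == "none" and rng.random() < 0.05:
            # Re-dispense after a long drug-free gap: a second episode the
            # cohort builder must ignore.
            gap = int(rng.integers(125, 200))
            later = index_date + pd.Timedelta(days=treat_end + gap + 1)
            if later <= study_end:
                rec.rx.append(
                    {
                        "patient_id": pid,
                        "drug_id": index_drug,
                        "dispense_date": _iso(later),
                        "days_supplied": config.refill_days,
                        "setting": "outpatient",
                    }
                )

        # Visits --------------------------------------------------------
        shape, scale = config.visit_interval_model
        day = 0
        fu_days = min(treat_end, (study_end - index_date).days)
        while day <= fu_days:
            rec.visits.append(
                {
                    "patient_id": pid,
                    "date": _iso(index_date + pd.Timedelta(days=day)),
                    "setting": "outpatient",
                    "admission_date": "",
                    "discharge_date": "",
                }
            )
            day += max(1, int(round(float(rng.gamma(shape, scale)))))
        if setting == "inpatient":
            stay = _lognormal_days(rng, 38.0, 0.4)
            rec.visits.append(
                {
                    "patient_id": pid,
                    "date": _iso(index_date),
                    "setting": "inpatient",
                    "admission_date": _iso(index_date),
                    "discharge_date": _iso(index_date + pd.Timedelta(days=stay)),
                }
            )

        # Ground truth --------------------------------------------------
        intended = [
            (regimens[li], entries[li], durations[li]) for li in range(n_levels)
        ]
        concordant: bool | None = None
        if exclusion == "none":
            concordant = _intended_concordance(intended, tiers)
        truths.append(
            GroundTruth(
                patient_id=pid,
                eligible=exclusion == "none",
                exclusion_reason=exclusion,
                intended_levels=intended if exclusion == "none" else [],
                intended_concordant=concordant,
            )
        )

    return rec.tables(), truths


def _pick_drug(rng: np.random.Generator, weights: dict[str, float], used: set[str]) -> str:
    for _ in range(100):
        d = _sample_weighted(rng, weights)
        if d not in used:
            return d
    pool = [d for d in weights if d not in used]
    if not pool:
        raise SimConfigError("drug weight pool exhausted; add more drugs")
    return str(rng.choice(pool))


def _emit_refills(
    rec: _Recorder,
    rng: np.random.Generator,
    pid: str,
    drug: str,
    index_date: pd.Timestamp,
    start: int,
    end: int,
    refill_days: int,
    setting: str,
    noisy: bool,
) -> None:
    """Dispenses covering day offsets [start, end] relative to the index.

    Clean mode emits exactly abutting refills; noisy mode inserts gaps of
    up to 10 days (inside the 14-day grace period) which stretch the
    calendar span of the same total supply.
    """
    day = start
    while day <= end:
        supply = min(refill_days, end - day + 1)
        rec.rx.append(
            {
                "patient_id": pid,
                "drug_id": drug,
                "dispense_date": _iso(index_date + pd.Timedelta(days=day)),
                "days_supplied": int(supply),
                "setting": setting,
            }
        )
        gap = int(rng.integers(0, 11)) if noisy else 0
        day += supply + gap


def _intended_concordance(
    intended: Sequence[tuple[frozenset[str], str, int]],
    tiers: CanmatTierTable,
) -> bool:
    regimen0, _, _ = intended[0]
    if len(regimen0) != 1:
        return False
    (index_drug,) = regimen0
    if tiers.monotherapy_status(index_drug) != "first":
        return False
    for li in range(1, min(len(intended), 3)):
        prev = intended[li - 1][0]
        reg, entry, _ = intended[li]
        new = reg - prev
        if len(new) >= 2:
            return False
        (drug,) = new
        if entry == "switch" and not tiers.switch_concordant(drug):
            return False
        if entry == "add_on" and not tiers.adjunct_concordant(drug):
            return False
    return True


def truths_to_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    """Flatten ground truth to a delimited-text-friendly table."""
    rows = []
    for t in truths:
        rows.append(
            {
                "patient_id": t.patient_id,
                "eligible": int(t.eligible),
                "exclusion_reason": t.exclusion_reason,
                "n_levels": len(t.intended_levels),
                "levels": "|".join(
                    f"{'+'.join(sorted(reg))};{entry};{dur}"
                    for reg, entry, dur in t.intended_levels
                ),
                "intended_concordant": (
                    "" if t.intended_concordant is None else int(t.intended_concordant)
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "eligible", "exclusion_reason",
            "n_levels", "levels", "intended_concordant",
        ],
    )


def write_tables(tables: dict[str, pd.DataFrame], outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)


def read_tables(indir) -> dict[str, pd.DataFrame]:
    from pathlib import Path

    ind = Path(indir)
    tables = {}
    for name in TABLE_NAMES:
        path = ind / f"{name}.tsv"
        tables[name] = (
            pd.read_csv(path, sep="\t", dtype={"patient_id": str}, keep_default_na=False)
            if path.exists()
            else pd.DataFrame()
        )
    return tables


# -- hand-built fixtures ---------------------------------------------------


def make_fixture(name: str) -> dict[str, pd.DataFrame]:
    """Small single-patient timelines with known classifications."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    rec = _Recorder()
    pid = "FX0001"
    index = pd.Timestamp("2016-03-01")
    rec.patients.append({"patient_id": pid, "birth_date": "1986-05-10", "sex": "F"})
    rec.dx.append({"patient_id": pid, "icd10_code": "F32.1", "date": _iso(index)})

    def rx(drug: str, day: int, supply: int) -> None:
        rec.rx.append(
            {
                "patient_id": pid,
                "drug_id": drug,
                "dispense_date": _iso(index + pd.Timedelta(days=day)),
                "days_supplied": supply,
                "setting": "outpatient",
            }
        )

    if name == "addon_35d_overlap":
        rx("escitalopram", 0, 60)  # covers [0, 59]
        rx("mirtazapine", 25, 35)  # covers [25, 59]: 35-day overlap
    elif name == "switch_20d_overlap":
        rx("escitalopram", 0, 40)  # covers [0, 39]
        rx("venlafaxine", 20, 40)  # overlap 20 < 30 -> switch
    elif name == "attempt_15d_supply":
        rx("escitalopram", 0, 60)
        rx("venlafaxine", 30, 15)  # 15 supplied days -> attempt
    elif name == "grace_gap_10d":
        rx("escitalopram", 0, 30)  # [0, 29]
        rx("escitalopram", 40, 30)  # 10 drug-free days <= 14 -> one interval [40, 69]
    elif name == "multi_switch_2drugs":
        rx("escitalopram", 0, 30)
        rx("venlafaxine", 30, 40)
        rx("mirtazapine", 33, 40)  # two new drugs within 14 days -> multi switch
    elif name == "washout_violation":
        rx("sertraline", -200, 28)  # AD 200 days before the candidate index
        rx("escitalopram", 0, 30)
    elif name == "episode_gap_130d":
        rx("escitalopram", 0, 30)  # supply ends day 29
        rx("escitalopram", 160, 30)  # 130 drug-free days -> episode break
    rec.visits.append(
        {
            "patient_id": pid,
            "date": _iso(index),
            "setting": "outpatient",
            "admission_date": "",
            "discharge_date": "",
        }
    )
    return rec.tables()
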