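"""Exposure-interval merging, change classification and treatment levels.

Dates are handled as integer day offsets internally (``pandas`` datetimes
at the boundary); every interval is closed and day-granular, so a d-day
supply dispensed on day s covers [s, s + d - 1].

Classification of a new drug against the current regimen:

* total merged supply < 30 days  -> attempt (level unchanged, drug never
  joins a regimen);
* otherwise, overlap of at least 30 days with every current regimen drug
  -> add-on (regimen grows);
* otherwise -> switch (regimen drugs with < 30 days of overlap are
  dropped; the new drug, plus any old drug that does sustain a 30-day
  overlap, form the next regimen).

New qualifying drugs whose merged runs start within 14 days of each other
are grouped into a single multi-drug transition.  Each switch or add-on
increments the treatment level by exactly one; attempts never do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

GRACE_DAYS = 14
OVERLAP_MIN_DAYS = 30
SUPPLY_MIN_DAYS = 30
EVENT_WINDOW_DAYS = 14

DURATION_BIN_EDGES = (14, 28, 42, 56)
DURATION_BINS = ("lt2w", "w2_4", "w4_6", "w6_8", "gt8w")


class PatternError(ValueError):
    pass


@dataclass(frozen=True)
class ExposureInterval:
    """A merged, grace-period-closed run of continuous exposure to one drug."""

    patient_id: str
    drug_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise PatternError(f"interval start {self.start} > end {self.end}")

    @property
    def supplied_days(self) -> int:
        return self.end - self.start + 1

    def overlap_days(self, other: "ExposureInterval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass(frozen=True)
class TransitionEvent:
    """A classified medication change."""

    event_date: int
    kind: str  # switch | add_on | attempt
    new_drugs: frozenset[str]
    dropped_drugs: frozenset[str]
    overlap_days: int

    @property
    def multi_drug(self) -> bool:
        return len(self.new_drugs) >= 2


@dataclass(frozen=True)
class LevelRecord:
    """One treatment level: regimen, how it was entered, and its duration."""

    level_index: int
    regimen: frozenset[str]
    entry_pattern: str  # initial | switch | add_on
    start: int
    end: int

    @property
    def duration_days(self) -> int:
        return self.end - self.start + 1

    @property
    def duration_bin(self) -> str:
        return bin_duration(self.duration_days)


def bin_duration(duration_days: int) -> str:
    """Map a duration in days to its week bin.

    Bins partition the positive integers: lt2w <=13, w2_4 14-27,
    w4_6 28-41, w6_8 42-55, gt8w >=56.
    """
    if duration_days < 1:
        raise PatternError(f"duration must be >= 1 day, got {duration_days}")
    for edge, label in zip(DURATION_BIN_EDGES, DURATION_BINS):
        if duration_days < edge:
            return label
    return DURATION_BINS[-1]


def merge_exposures(
    dispenses: Sequence[tuple[int, int]],
    grace_days: int = GRACE_DAYS,
    patient_id: str = "",
    drug_id: str = "",
) -> list[ExposureInterval]:
    """Merge one patient-drug's (dispense_day, days_supplied) pairs.

    Supply runs that overlap, abut, or are separated by at most
    ``grace_days`` drug-free days collapse into a single interval whose
    end is the furthest covered day.
    """
    runs: list[list[int]] = []
    for day, supplied in sorted(dispenses):
        if supplied < 1:
            raise PatternError(
                f"days_supplied must be positive, got {supplied} for {drug_id or 'drug'}"
            )
        end = day + supplied - 1
        if runs and day - runs[-1][1] - 1 <= grace_days:
            runs[-1][1] = max(runs[-1][1], end)
        else:
            runs.append([day, end])
    return [
        ExposureInterval(patient_id=patient_id, drug_id=drug_id, start=s, end=e)
        for s, e in runs
    ]


def _coverage_overlap(a: Iterable[ExposureInterval], b: Iterable[ExposureInterval]) -> int:
    """Total covered-day overlap between two sets of merged intervals."""
    total = 0
    for x in a:
        for y in b:
            total += x.overlap_days(y)
    return total


def classify_change(
    regimen_intervals: dict[str, list[ExposureInterval]],
    candidate: ExposureInterval,
    overlap_min: int = OVERLAP_MIN_DAYS,
    supply_min: int = SUPPLY_MIN_DAYS,
) -> TransitionEvent:
    """Classify a single candidate new-drug interval against the regimen."""
    if candidate.drug_id in regimen_intervals:
        raise PatternError(f"candidate {candidate.drug_id!r} already in regimen")
    if candidate.supplied_days < supply_min:
        return TransitionEvent(
            event_date=candidate.start,
            kind="attempt",
            new_drugs=frozenset({candidate.drug_id}),
            dropped_drugs=frozenset(),
            overlap_days=_coverage_overlap(
                [candidate], [iv for ivs in regimen_intervals.values() for iv in ivs]
            ),
        )
    overlaps = {
        drug: _coverage_overlap([candidate], ivs)
        for drug, ivs in regimen_intervals.items()
    }
    dropped = frozenset(d for d, o in overlaps.items() if o < overlap_min)
    kind = "add_on" if not dropped else "switch"
    return TransitionEvent(
        event_date=candidate.start,
        kind=kind,
        new_drugs=frozenset({candidate.drug_id}),
        dropped_drugs=dropped,
        overlap_days=min(overlaps.values(), default=0),
    )


def _clip(iv: ExposureInterval, lo: int, hi: int) -> ExposureInterval | None:
    s, e = max(iv.start, lo), min(iv.end, hi)
    if s > e:
        return None
    return ExposureInterval(iv.patient_id, iv.drug_id, s, e)


def build_levels(
    prescriptions: Sequence[tuple[str, int, int]],
    index_day: int,
    follow_up_end: int,
    *,
    grace_days: int = GRACE_DAYS,
    overlap_min: int = OVERLAP_MIN_DAYS,
    supply_min: int = SUPPLY_MIN_DAYS,
    event_window_days: int = EVENT_WINDOW_DAYS,
    patient_id: str = "",
) -> tuple[list[LevelRecord], list[TransitionEvent]]:
    """Scan one patient's (drug, dispense_day, days_supplied) stream.

    Returns the ordered treatment levels and every classified transition
    (including attempts).  Level 1 is the regimen active on the index
    day; the last level always ends at ``follow_up_end`` so level
    durations partition the follow-up exactly.
    """
    by_drug: dict[str, list[tuple[int, int]]] = {}
    for drug, day, supplied in prescriptions:
        by_drug.setdefault(drug, []).append((day, supplied))
    merged: dict[str, list[ExposureInterval]] = {}
    for drug, disp in by_drug.items():
        ivs = merge_exposures(disp, grace_days, patient_id=patient_id, drug_id=drug)
        clipped = [c for iv in ivs if (c := _clip(iv, index_day, follow_up_end))]
        if clipped:
            merged[drug] = clipped

    regimen = {
        drug
        for drug, ivs in merged.items()
        if any(iv.start <= index_day <= iv.end for iv in ivs)
    }
    if not regimen:
        raise PatternError(f"no exposure covering the index day for patient {patient_id!r}")

    # Candidate starts: merged runs beginning after the index day.  A run of
    # a drug currently in the regimen is a continuation, not a change.
    # Overlap is always measured against a drug's full merged coverage.
    candidates = sorted(
        (iv.start, drug, iv)
        for drug, ivs in merged.items()
        for iv in ivs
        if iv.start > index_day
    )

    levels: list[LevelRecord] = [
        LevelRecord(1, frozenset(regimen), "initial", index_day, follow_up_end)
    ]
    events: list[TransitionEvent] = []
    consumed: set[int] = set()
    i = 0
    while i < len(candidates):
        if i in consumed:
            i += 1
            continue
        start, drug, iv = candidates[i]
        if drug in regimen:
            i += 1
            continue
        if iv.supplied_days < supply_min:
            events.append(
                classify_change(
                    {d: merged[d] for d in regimen}, iv, overlap_min, supply_min
                )
            )
            i += 1
            continue
        # Group qualifying new drugs starting within the event window of the
        # first qualifying candidate.  Attempts are never grouped, so removing
        # them cannot move an event date.
        group = {drug: iv}
        j = i + 1
        while j < len(candidates) and candidates[j][0] - start <= event_window_days:
            if j not in consumed:
                _, d2, iv2 = candidates[j]
                if (
                    d2 not in regimen
                    and d2 not in group
                    and iv2.supplied_days >= supply_min
                ):
                    group[d2] = iv2
                    consumed.add(j)
            j += 1
        overlaps = {
            d: min(_coverage_overlap([g], merged[d]) for g in group.values())
            for d in regimen
        }
        dropped = frozenset(d for d, o in overlaps.items() if o < overlap_min)
        kind = "add_on" if not dropped else "switch"
        event = TransitionEvent(
            event_date=start,
            kind=kind,
            new_drugs=frozenset(group),
            dropped_drugs=dropped,
            overlap_days=min(overlaps.values(), default=0),
        )
        events.append(event)
        regimen = (regimen - dropped) | set(group)
        prev = levels[-1]
        levels[-1] = LevelRecord(
            prev.level_index, prev.regimen, prev.entry_pattern, prev.start, start - 1
        )
        levels.append(
            LevelRecord(prev.level_index + 1, frozenset(regimen), kind, start, follow_up_end)
        )
        i += 1
    return levels, events


# -- table-level driver ----------------------------------------------------


def run_pattern_engine(
    cohort: pd.DataFrame,
    prescriptions: pd.DataFrame,
    catalog,
    *,
    grace_days: int = GRACE_DAYS,
    overlap_min: int = OVERLAP_MIN_DAYS,
    supply_min: int = SUPPLY_MIN_DAYS,
    event_window_days: int = EVENT_WINDOW_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build levels and transitions tables for every eligible cohort row.

    ``cohort`` must carry patient_id, index_date, follow_up_end and
    exclusion_reason; only antidepressant prescriptions (per ``catalog``)
    participate in level construction.
    """
    # Adjunctive agents (antipsychotics, mood stabilizers, ...) count as
    # regimen changes, so every catalogued drug participates here; only the
    # index/washout/episode logic is antidepressant-specific.
    rx = prescriptions.copy()
    rx["dispense_date"] = pd.to_datetime(rx["dispense_date"])
    rx = rx[rx["drug_id"].map(lambda d: d in catalog)]
    eligible = cohort[cohort["exclusion_reason"] == "none"]
    epoch = pd.Timestamp("2000-01-01")
    grouped = dict(list(rx.groupby("patient_id")))
    level_rows: list[dict] = []
    event_rows: list[dict] = []
    for row in eligible.itertuples(index=False):
        pid = row.patient_id
        sub = grouped.get(pid)
        if sub is None:
            continue
        index_day = (pd.Timestamp(row.index_date) - epoch).days
        fu_end = (pd.Timestamp(row.follow_up_end) - epoch).days
        stream = [
            (r.drug_id, (r.dispense_date - epoch).days, int(r.days_supplied))
            for r in sub.itertuples(index=False)
        ]
        levels, events = build_levels(
            stream,
            index_day,
            fu_end,
            grace_days=grace_days,
            overlap_min=overlap_min,
            supply_min=supply_min,
            event_window_days=event_window_days,
            patient_id=pid,
        )
        for lv in levels:
            level_rows.append(
                {
                    "patient_id": pid,
                    "level_index": lv.level_index,
                    "regimen": "+".join(sorted(lv.regimen)),
                    "entry_pattern": lv.entry_pattern,
                    "start": (epoch + pd.Timedelta(days=lv.start)).date().isoformat(),
                    "end": (epoch + pd.Timedelta(days=lv.end)).date().isoformat(),
                    "duration_days": lv.duration_days,
                    "duration_bin": lv.duration_bin,
                }
            )
        for k, ev in enumerate(events):
            event_rows.append(
                {
                    "patient_id": pid,
                    "event_index": k,
                    "event_date": (epoch + pd.Timedelta(days=ev.event_date)).date().isoformat(),
                    "kind": ev.kind,
                    "new_drugs": "+".join(sorted(ev.new_drugs)),
                    "dropped_drugs": "+".join(sorted(ev.dropped_drugs)),
                    "multi_drug": int(ev.multi_drug),
                    "overlap_days": ev.overlap_days,
                }
            )
    level_cols = [
        "patient_id", "level_index", "regimen", "entry_pattern",
        "start", "end", "duration_days", "duration_bin",
    ]
    event_cols = [
        "patient_id", "event_index", "event_date", "kind",
        "new_drugs", "dropped_drugs", "multi_drug", "overlap_days",
    ]
    levels_df = pd.DataFrame(level_rows, columns=level_cols)
    events_df = pd.DataFrame(event_rows, columns=event_cols)
    return levels_df, events_df
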