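"""Per-patient guideline-concordance labelling over the first three levels.

A patient is concordant overall only when every level actually reached
(up to level 3) agrees with the stepwise recommendation: a first-line
drug at level 1, and at each later step either a switch to an eligible
drug or an add-on of a listed adjunct.  Multi-drug switches and
multi-drug add-ons are discordant by definition.  Treatment duration
never affects the flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .canmat_rules import CanmatTierTable

MAX_LEVELS_ANALYZED = 3

REASONS = (
    "nonrecommended_initial",
    "nonrecommended_switch_drug",
    "multi_switch",
    "nonrecommended_adjunct",
    "multi_add",
)


@dataclass(frozen=True)
class ConcordanceResult:
    patient_id: str
    level_flags: tuple[str, ...]  # concordant | discordant per realized level <= 3
    overall: bool
    discordance_reasons: frozenset[str]
    optimized: bool  # reached level >= 2

    @property
    def n_levels_scored(self) -> int:
        return len(self.level_flags)


def classify_level1(index_drug: str, tiers: CanmatTierTable) -> tuple[bool, str | None]:
    """Level 1 is concordant iff the index drug is first-line monotherapy."""
    ok = tiers.monotherapy_status(index_drug) == "first"
    return ok, None if ok else "nonrecommended_initial"


def classify_transition(
    kind: str,
    new_drugs: frozenset[str] | set[str],
    tiers: CanmatTierTable,
) -> tuple[bool, set[str]]:
    """Score one switch or add-on against the tier table.

    Attempts are not transitions and are rejected.
    """
    if kind not in {"switch", "add_on"}:
        raise ValueError(f"not a level transition: kind={kind!r}")
    new_drugs = set(new_drugs)
    if kind == "switch":
        if len(new_drugs) >= 2:
            return False, {"multi_switch"}
        (drug,) = new_drugs
        if tiers.switch_concordant(drug):
            return True, set()
        return False, {"nonrecommended_switch_drug"}
    if len(new_drugs) >= 2:
        return False, {"multi_add"}
    (drug,) = new_drugs
    if tiers.adjunct_concordant(drug):
        return True, set()
    return False, {"nonrecommended_adjunct"}


def classify_patient(
    patient_id: str,
    index_drug: str,
    transitions: list[tuple[str, frozenset[str]]],
    tiers: CanmatTierTable,
    max_levels: int = MAX_LEVELS_ANALYZED,
) -> ConcordanceResult:
    """Combine the level-1 flag with the transitions into levels 2..max_levels.

    ``transitions`` is the ordered list of (kind, new_drugs) for the
    patient's switch/add-on events; attempts must already be filtered
    out.  Levels beyond ``max_levels`` are ignored.
    """
    flags: list[str] = []
    reasons: set[str] = set()
    ok1, reason1 = classify_level1(index_drug, tiers)
    flags.append("concordant" if ok1 else "discordant")
    if reason1:
        reasons.add(reason1)
    for kind, new_drugs in transitions[: max_levels - 1]:
        ok, rs = classify_transition(kind, new_drugs, tiers)
        flags.append("concordant" if ok else "discordant")
        reasons |= rs
    overall = all(f == "concordant" for f in flags)
    return ConcordanceResult(
        patient_id=patient_id,
        level_flags=tuple(flags),
        overall=overall,
        discordance_reasons=frozenset(reasons),
        optimized=len(transitions) >= 1,
    )


def run_concordance(
    cohort: pd.DataFrame,
    transitions: pd.DataFrame,
    tiers: CanmatTierTable,
    max_levels: int = MAX_LEVELS_ANALYZED,
) -> pd.DataFrame:
    """Classify every eligible cohort patient; one output row per patient.

    Output columns: patient_id, level{1..3}_flag (empty when the level was
    not reached), overall (0/1), reasons ('|'-joined), optimized (0/1),
    first_transition_kind, first_transition_multi.
    """
    eligible = cohort[cohort["exclusion_reason"] == "none"]
    tr = transitions[transitions["kind"] != "attempt"]
    tr_by_pt: dict[str, list] = {
        pid: list(sub.sort_values("event_index").itertuples(index=False))
        for pid, sub in tr.groupby("patient_id")
    }
    rows = []
    for row in eligible.itertuples(index=False):
        pid = row.patient_id
        evs = tr_by_pt.get(pid, [])
        trans = [(e.kind, frozenset(e.new_drugs.split("+"))) for e in evs]
        res = classify_patient(pid, row.index_drug, trans, tiers, max_levels)
        out = {
            "patient_id": pid,
            "overall": int(res.overall),
            "reasons": "|".join(sorted(res.discordance_reasons)),
            "optimized": int(res.optimized),
            "n_levels_scored": res.n_levels_scored,
            "first_transition_kind": evs[0].kind if evs else "",
            "first_transition_multi": int(evs[0].multi_drug) if evs else 0,
        }
        for i in range(max_levels):
            out[f"level{i + 1}_flag"] = (
                res.level_flags[i] if i < len(res.level_flags) else ""
            )
        rows.append(out)
    cols = (
        ["patient_id"]
        + [f"level{i + 1}_flag" for i in range(max_levels)]
        + [
            "overall",
            "reasons",
            "optimized",
            "n_levels_scored",
            "first_transition_kind",
            "first_transition_multi",
        ]
    )
    return pd.DataFrame(rows, columns=cols)
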