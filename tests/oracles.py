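"""Independent brute-force references used by the test suite.

These deliberately work on per-day sets and explicit day loops instead of
the interval arithmetic used by the package, so that agreement between
the two is informative.
"""

from __future__ import annotations

from math import comb


def day_runs(dispenses, grace_days=14):
    """Merged coverage runs of one drug from raw (day, supply) pairs.

    A run is the span [first, last] of covered days where consecutive
    covered days are separated by at most ``grace_days`` uncovered days.
    """
    covered = sorted(
        {d for day, supply in dispenses for d in range(day, day + supply)}
    )
    runs = []
    for d in covered:
        if runs and d - runs[-1][1] - 1 <= grace_days:
            runs[-1][1] = d
        else:
            runs.append([d, d])
    return [(a, b) for a, b in runs]


def clip_runs(runs, lo, hi):
    out = []
    for a, b in runs:
        a2, b2 = max(a, lo), min(b, hi)
        if a2 <= b2:
            out.append((a2, b2))
    return out


def run_days(runs):
    days = set()
    for a, b in runs:
        days.update(range(a, b + 1))
    return days


def simulate_levels(
    prescriptions,
    index_day,
    follow_up_end,
    grace_days=14,
    overlap_min=30,
    supply_min=30,
    event_window_days=14,
):
    """Day-set reference simulator of the change-classification rules.

    ``prescriptions``: iterable of (drug, dispense_day, days_supplied).
    Returns (levels, events); levels as (regimen frozenset, entry, start,
    end), events as (day, kind, new_drugs frozenset).
    """
    by_drug = {}
    for drug, day, supply in prescriptions:
        by_drug.setdefault(drug, []).append((day, supply))
    runs = {
        drug: clip_runs(day_runs(disp, grace_days), index_day, follow_up_end)
        for drug, disp in by_drug.items()
    }
    runs = {d: r for d, r in runs.items() if r}
    cover = {d: run_days(r) for d, r in runs.items()}

    regimen = {d for d, dayset in cover.items() if index_day in dayset}
    if not regimen:
        raise ValueError("no coverage on index day")

    candidates = sorted(
        (a, drug, (a, b)) for drug, rs in runs.items() for a, b in rs if a > index_day
    )
    levels = [[frozenset(regimen), "initial", index_day, follow_up_end]]
    events = []
    consumed = set()
    for i, (start, drug, (a, b)) in enumerate(candidates):
        if i in consumed or drug in regimen:
            continue
        length = b - a + 1
        if length < supply_min:
            events.append((start, "attempt", frozenset({drug})))
            continue
        group = {drug: set(range(a, b + 1))}
        for j in range(i + 1, len(candidates)):
            s2, d2, (a2, b2) = candidates[j]
            if s2 - start > event_window_days:
                break
            if (
                j not in consumed
                and d2 not in regimen
                and d2 not in group
                and b2 - a2 + 1 >= supply_min
            ):
                group[d2] = set(range(a2, b2 + 1))
                consumed.add(j)
        dropped = set()
        for r in regimen:
            worst = min(len(cover[r] & g) for g in group.values())
            if worst < overlap_min:
                dropped.add(r)
        kind = "add_on" if not dropped else "switch"
        events.append((start, kind, frozenset(group)))
        regimen = (regimen - dropped) | set(group)
        levels[-1][3] = start - 1
        levels.append([frozenset(regimen), kind, start, follow_up_end])
    return (
        [(reg, entry, s, e) for reg, entry, s, e in levels],
        events,
    )


def episode_end_by_day_walk(dispenses, index_day, study_end_day, gap_days=120):
    """Walk calendar days to find the first-episode end.

    ``dispenses``: (day, supply) pairs for antidepressants.  The episode
    ends at the last covered day of the supply run after which more than
    ``gap_days`` drug-free days pass before the next dispense.
    """
    future = sorted((d, s) for d, s in dispenses if d >= index_day)
    if not future:
        raise ValueError("no dispense on or after index day")
    supply_end = index_day - 1
    i = 0
    day = index_day
    horizon = max(d + s for d, s in future) + gap_days + 2
    free = 0
    while day <= horizon:
        dispensed_today = False
        while i < len(future) and future[i][0] == day:
            if free > gap_days:
                return min(supply_end, study_end_day)
            d, s = future[i]
            supply_end = max(supply_end, d + s - 1)
            dispensed_today = True
            i += 1
        if dispensed_today:
            free = 0
        if day > supply_end:
            free += 1
        day += 1
    return min(supply_end, study_end_day)


def exact_trend_tail(counts, totals, scores=None):
    """Exact conditional permutation distribution of the trend statistic.

    Enumerates all success allocations with the observed total fixed
    (multivariate hypergeometric weights) and returns
    (mean_T, var_T, two_sided_tail_probability).
    Only practical for 3 groups with small totals.
    """
    assert len(counts) == len(totals) == 3
    s = scores or (1, 2, 3)
    S, N = sum(counts), sum(totals)
    pbar = S / N

    def stat(x):
        return sum(si * (xi - ni * pbar) for si, xi, ni in zip(s, x, totals))

    t_obs = stat(counts)
    denom = comb(N, S)
    mean = var = tail = 0.0
    for x1 in range(0, totals[0] + 1):
        for x2 in range(0, totals[1] + 1):
            x3 = S - x1 - x2
            if not 0 <= x3 <= totals[2]:
                continue
            w = comb(totals[0], x1) * comb(totals[1], x2) * comb(totals[2], x3) / denom
            t = stat((x1, x2, x3))
            mean += w * t
            var += w * t * t
            if abs(t) >= abs(t_obs) - 1e-12:
                tail += w
    var -= mean**2
    return mean, var, tail
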