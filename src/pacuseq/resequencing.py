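"""OR-day reconstruction, schedule simulation and risk-based case resequencing.

An OR day is all cases for one surgeon on one date.  It is *full* when its
scheduled content extends at least to 3 pm.  The counterfactual exercise:
re-order each full day's cases by predicted risk of prolonged PACU stay
(highest risk first), replay the day as a sequential schedule, and compare
how often any patient is still in the PACU past 7 pm against the historic
order.  A case's duration and PACU LOS are treated as intrinsic to the case
and travel with it when it is moved.

Clock times are minutes after midnight throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
from scipy import stats

FULL_DAY_CUTOFF_MIN = 15 * 60.0  # 3 pm
AFTER_HOURS_CUTOFF_MIN = 19 * 60.0  # 7 pm
_BRUTE_FORCE_MAX_CASES = 8


def parse_clock(text: str) -> float:
    """'HH:MM' -> minutes after midnight."""
    hh, mm = text.split(":")
    return int(hh) * 60.0 + float(mm)


def format_clock(minutes: float) -> str:
    """Minutes after midnight -> 'HH:MM' (rounded to the nearest minute)."""
    total = int(round(minutes))
    return f"{total // 60:02d}:{total % 60:02d}"


@dataclass
class ORDay:
    """Same-surgeon, same-date case list in historic scheduled order."""

    day_id: str
    date: Date
    surgeon_id: str
    case_ids: list
    day_start: float
    full_day: bool


@dataclass
class ScheduleResult:
    """Replay of one OR day under a given case ordering."""

    day_id: str
    ordering: list
    surgery_start: dict
    surgery_end: dict
    pacu_exit: dict
    latest_surgery_end: float
    latest_pacu_exit: float


@dataclass
class ResequencingReport:
    n_days: int
    n_days_resequenced: int
    n_cases_resequenced: int
    per_day: list  # (day_id, historic_after_hours, resequenced_after_hours, resequenced)
    table_2x2: list  # [[historic_yes, historic_no], [reseq_yes, reseq_no]]
    chi2_stat: float
    p_value: float
    cutoff: float
    historic_after_hours: int = 0
    resequenced_after_hours: int = 0

    def summary_table(self) -> str:
        """Human-readable comparison table (historic vs resequenced)."""
        h, r = self.historic_after_hours, self.resequenced_after_hours
        n = self.n_days
        lines = [
            "Historic vs ML-resequenced after-hours PACU occupancy",
            f"  Total number of OR days            {n}",
            f"  OR days resequenced                {self.n_days_resequenced}"
            f" ({100 * self.n_days_resequenced / n:.1f}%)"
            f" [{self.n_cases_resequenced} cases moved]",
            f"  After-hours days, historic order   {h} ({100 * h / n:.1f}%)",
            f"  After-hours days, resequenced      {r} ({100 * r / n:.1f}%)",
            f"  Chi-square = {self.chi2_stat:.3f}, p = {self.p_value:.3g}"
            f" (after-hours cutoff {format_clock(self.cutoff)})",
        ]
        return "\n".join(lines)


def reconstruct_or_days(
    cases,
    full_day_cutoff: float = FULL_DAY_CUTOFF_MIN,
    rule: str = "scheduled_end",
):
    """Group cases into OR days by (date, surgeon) and flag full days.

    Returns ``(full_days, other_days)``; only full days enter the
    resequencing analysis.  ``rule`` decides fullness: ``"scheduled_end"``
    (default) requires the scheduled end of the last case to be at or after
    the cutoff; ``"last_start"`` requires the last case's scheduled *start*
    to be at or after it.

    Raises on overlapping scheduled cases within a day.
    """
    if rule not in ("scheduled_end", "last_start"):
        raise ValueError(f"unknown full-day rule {rule!r}")
    groups = {}
    for c in cases:
        groups.setdefault((c.date, c.surgeon_id), []).append(c)

    full, other = [], []
    for i, key in enumerate(sorted(groups)):
        date, surgeon = key
        day_cases = sorted(groups[key], key=lambda c: c.scheduled_start)
        for a, b in zip(day_cases, day_cases[1:]):
            if a.scheduled_start + a.scheduled_duration > b.scheduled_start + 1e-9:
                raise ValueError(
                    f"overlapping scheduled cases on {date} / {surgeon}: "
                    f"{a.case_id} (ends {format_clock(a.scheduled_start + a.scheduled_duration)}) "
                    f"overlaps {b.case_id} (starts {format_clock(b.scheduled_start)})"
                )
        last = day_cases[-1]
        mark = (
            last.scheduled_start + last.scheduled_duration
            if rule == "scheduled_end"
            else last.scheduled_start
        )
        day = ORDay(
            day_id=f"D{i:05d}",
            date=date,
            surgeon_id=surgeon,
            case_ids=[c.case_id for c in day_cases],
            day_start=day_cases[0].scheduled_start,
            full_day=bool(mark >= full_day_cutoff),
        )
        (full if day.full_day else other).append(day)
    return full, other


def simulate_schedule(day, ordering, los_lookup, turnover: float = 0.0,
                      duration_lookup=None) -> ScheduleResult:
    """Replay a day as a back-to-back sequential schedule under ``ordering``.

    Cases run consecutively from ``day.day_start`` separated by ``turnover``
    minutes; each patient leaves the PACU ``pacu_los`` minutes after their
    surgery ends.  ``duration_lookup`` maps case id to the duration used for
    the replay (actual where recorded, else scheduled) and must cover every
    case in the day.
    """
    if sorted(ordering) != sorted(day.case_ids):
        raise ValueError("ordering must be a permutation of the day's case ids")
    if duration_lookup is None:
        raise ValueError("duration_lookup is required (scheduled or actual durations)")
    missing = [cid for cid in ordering if cid not in los_lookup]
    if missing:
        raise ValueError(f"missing PACU LOS for case(s): {missing}")

    starts, ends, exits = {}, {}, {}
    t = day.day_start
    for cid in ordering:
        starts[cid] = t
        ends[cid] = t + float(duration_lookup[cid])
        exits[cid] = ends[cid] + float(los_lookup[cid])
        t = ends[cid] + turnover
    # the makespan is permutation-invariant by construction; fsum keeps it
    # exactly so in floating point as well
    latest_end = day.day_start + math.fsum(
        float(duration_lookup[cid]) for cid in ordering
    ) + turnover * (len(ordering) - 1)
    return ScheduleResult(
        day_id=day.day_id,
        ordering=list(ordering),
        surgery_start=starts,
        surgery_end=ends,
        pacu_exit=exits,
        latest_surgery_end=latest_end,
        latest_pacu_exit=max(exits.values()),
    )


def resequence_by_risk(day, risk) -> list:
    """Order the day's cases by predicted risk, descending; stable in ties.

    Ties keep historic position, so a constant risk vector reproduces the
    historic order exactly.
    """
    missing = [cid for cid in day.case_ids if cid not in risk]
    if missing:
        raise ValueError(f"missing risk value for case(s): {missing}")
    return sorted(day.case_ids, key=lambda cid: -float(risk[cid]))


def counts_as_resequenced(day, ordering, risk, threshold: float = 0.5) -> bool:
    """A day is 'resequenced' iff the order changed and at least one of its
    cases is predicted prolonged at the classification threshold."""
    changed = list(ordering) != list(day.case_ids)
    any_flagged = any(float(risk[cid]) >= threshold for cid in day.case_ids)
    return changed and any_flagged


def after_hours_flag(schedule: ScheduleResult,
                     cutoff: float = AFTER_HOURS_CUTOFF_MIN) -> bool:
    """True iff any PACU exit falls strictly past the cutoff (7 pm default).

    An exit at exactly the cutoff does not count as after-hours.
    """
    return bool(schedule.latest_pacu_exit > cutoff)


def brute_force_min_latest_exit(day, los_lookup, turnover: float = 0.0,
                                duration_lookup=None):
    """Exhaustive-permutation minimum of the latest PACU exit (oracle).

    Guarded to days of <= 8 cases.  The classical longest-tail-first result
    says sorting by true PACU LOS descending attains this minimum; this
    enumerator is the independent check of that ordering.
    """
    if len(day.case_ids) > _BRUTE_FORCE_MAX_CASES:
        raise ValueError(
            f"day has {len(day.case_ids)} cases; exhaustive search is limited to "
            f"{_BRUTE_FORCE_MAX_CASES}. Sort by PACU LOS descending instead."
        )
    best_val, best_perm = float("inf"), None
    for perm in itertools.permutations(day.case_ids):
        val = simulate_schedule(day, list(perm), los_lookup, turnover,
                                duration_lookup).latest_pacu_exit
        if val < best_val - 1e-12:
            best_val, best_perm = val, list(perm)
    return best_val, best_perm


def chi2_2x2(table, yates: bool = False):
    """Chi-square test of independence on a 2x2 table, 1 df.

    Degenerate tables with a zero margin (e.g. no after-hours days in either
    arm) carry no evidence of association: statistic 0, p = 1.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(arr, correction=yates)
    return float(stat), float(p)


def compare_schedules(
    days,
    risk,
    cutoff: float = AFTER_HOURS_CUTOFF_MIN,
    turnover: float = 0.0,
    los_lookup=None,
    duration_lookup=None,
    threshold: float = 0.5,
    yates: bool = False,
) -> ResequencingReport:
    """Historic vs risk-resequenced after-hours comparison across full days.

    Builds the 2x2 contingency table (after-hours yes/no by historic vs
    resequenced arm) and tests independence with a 1-df chi-square (no
    continuity correction by default; Yates by flag).
    """
    days = [d for d in days if d.full_day]
    if not days:
        raise ValueError("no full OR days to analyze")

    per_day = []
    n_days_reseq = 0
    n_cases_reseq = 0
    for day in days:
        historic = simulate_schedule(day, day.case_ids, los_lookup, turnover,
                                     duration_lookup)
        ordering = resequence_by_risk(day, risk)
        reseq = simulate_schedule(day, ordering, los_lookup, turnover,
                                  duration_lookup)
        h_flag = after_hours_flag(historic, cutoff)
        r_flag = after_hours_flag(reseq, cutoff)
        was_reseq = counts_as_resequenced(day, ordering, risk, threshold)
        if was_reseq:
            n_days_reseq += 1
            n_cases_reseq += sum(
                1 for pos, cid in enumerate(ordering) if day.case_ids[pos] != cid
            )
        per_day.append((day.day_id, h_flag, r_flag, was_reseq))

    n = len(days)
    h_yes = sum(1 for _, h, _, _ in per_day if h)
    r_yes = sum(1 for _, _, r, _ in per_day if r)
    table = [[h_yes, n - h_yes], [r_yes, n - r_yes]]
    stat, p = chi2_2x2(table, yates=yates)
    return ResequencingReport(
        n_days=n,
        n_days_resequenced=n_days_reseq,
        n_cases_resequenced=n_cases_reseq,
        per_day=per_day,
        table_2x2=table,
        chi2_stat=stat,
        p_value=p,
        cutoff=cutoff,
        historic_after_hours=h_yes,
        resequenced_after_hours=r_yes,
    )
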