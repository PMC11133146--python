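"""Behavioural measures: adaptation index, sessionization, engagement
indices, devalued-entry proportion, exclusion and quartile rules."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .agents import ParticipantLog
from .task_engine import GroupSchedule, Manipulation, TaskConfig, schedule_for_group

__all__ = [
    "AdaptationIndex",
    "SessionSet",
    "adaptation_index",
    "sessionize",
    "engagement_indices",
    "devalued_proportion",
    "exclusion_filter",
    "quartile_groups",
    "entries_under_manipulation",
    "count_dataset",
    "metrics_table",
]

SESSION_THRESHOLD = 300.0   # seconds; gaps >= threshold split sessions


@dataclass(frozen=True)
class AdaptationIndex:
    """Behavioural adaptation (goal-directedness) index.

    value = (sqrt(mu_valued) - sqrt(devalued)) / (sqrt(mu_valued) + sqrt(devalued))

    where mu_valued averages the entry counts on the control days before
    and after devaluation.  Ranges over [-1, 1]: 1 means no entries after
    devaluation (utter goal-directedness), values near 0 mean habitual
    responding.
    """

    valued_pre: float
    valued_post: float
    devalued: float

    @property
    def mu_valued(self) -> float:
        return (self.valued_pre + self.valued_post) / 2.0

    @property
    def value(self) -> float:
        a = np.sqrt(self.mu_valued)
        b = np.sqrt(self.devalued)
        return float((a - b) / (a + b))


def adaptation_index(valued_pre: float, valued_post: float,
                     devalued: float) -> AdaptationIndex:
    if min(valued_pre, valued_post, devalued) < 0:
        raise ValueError("entry counts must be nonnegative")
    if valued_pre + valued_post == 0 and devalued == 0:
        raise ValueError("adaptation index undefined: no entries on any "
                         "manipulation day")
    return AdaptationIndex(valued_pre, valued_post, devalued)


@dataclass
class SessionSet:
    """Partition of a timestamp stream into self-initiated sessions."""

    sessions: list[np.ndarray]
    threshold: float = SESSION_THRESHOLD

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    @property
    def entries_per_session_avg(self) -> float:
        if not self.sessions:
            return float("nan")
        return float(np.mean([len(s) for s in self.sessions]))

    def flatten(self) -> np.ndarray:
        if not self.sessions:
            return np.empty(0)
        return np.concatenate(self.sessions)


def sessionize(timestamps: Sequence[float],
               threshold: float = SESSION_THRESHOLD) -> SessionSet:
    """Split ordered timestamps into sessions at gaps >= threshold.

    Consecutive entries strictly less than ``threshold`` seconds apart
    belong to the same session (a 300 s gap starts a new one).
    """
    ts = np.asarray(timestamps, dtype=float)
    if ts.size and np.any(np.diff(ts) < 0):
        raise ValueError("timestamps must be sorted")
    if ts.size == 0:
        return SessionSet([], threshold)
    breaks = np.flatnonzero(np.diff(ts) >= threshold) + 1
    return SessionSet([np.asarray(s) for s in np.split(ts, breaks)], threshold)


def engagement_indices(log: ParticipantLog, schedule: GroupSchedule,
                       threshold: float = SESSION_THRESHOLD,
                       exclude_all_manipulation_days: bool = False) -> dict:
    """Per-participant engagement summary.

    ``avg_daily_entries`` excludes the devaluation day (the robustness
    variant excludes every manipulation day); session indices are
    averaged over the days used.  ``baseline_entries_pre_devaluation_day``
    counts post-manipulation entries on the control day preceding
    devaluation.
    """
    counts = log.daily_counts(schedule.n_days)
    if counts.sum() == 0:
        raise ValueError("log has no entries")
    dev_day = schedule.devaluation_day
    if exclude_all_manipulation_days:
        skip = {d for d, m in schedule.manipulation_calendar.items()
                if m is not Manipulation.NONE}
    else:
        skip = {dev_day}
    used_days = [d for d in range(1, schedule.n_days + 1) if d not in skip]

    day_ts: dict[int, list[float]] = {d: [] for d in range(1, schedule.n_days + 1)}
    for ev in log.events:
        day_ts[ev.day_index].append(ev.timestamp)

    daily_sessions, per_session = [], []
    for d in used_days:
        ss = sessionize(sorted(day_ts[d]), threshold)
        daily_sessions.append(ss.n_sessions)
        if ss.n_sessions:
            per_session.append(ss.entries_per_session_avg)
    manip = entries_under_manipulation(log, schedule)
    return {
        "first_day_entries": int(counts[0]),
        "avg_daily_entries": float(np.mean([counts[d - 1] for d in used_days])),
        "daily_sessions_avg": float(np.mean(daily_sessions)),
        "entries_per_session_avg": float(np.mean(per_session)) if per_session
                                   else float("nan"),
        "baseline_entries_pre_devaluation_day": manip["control_pre"],
    }


def devalued_proportion(still_valued: float, devalued: float) -> float:
    """Fraction still_valued / (still_valued + devalued), in [0, 1]."""
    if still_valued < 0 or devalued < 0:
        raise ValueError("counts must be nonnegative")
    total = still_valued + devalued
    if total == 0:
        raise ValueError("proportion undefined for zero counts")
    return float(still_valued / total)


def exclusion_filter(log: ParticipantLog, schedule: GroupSchedule,
                     config: Optional[TaskConfig] = None) -> dict:
    """Compliance rule: at least ``min_daily_entries`` on every day."""
    minimum = (config or TaskConfig()).min_daily_entries
    counts = log.daily_counts(schedule.n_days)
    bad = np.flatnonzero(counts < minimum)
    return {"included": bad.size == 0,
            "first_violation_day": int(bad[0]) + 1 if bad.size else None}


def quartile_groups(baseline_counts: pd.Series,
                    groups: Optional[pd.Series] = None,
                    within_group: bool = True) -> pd.DataFrame:
    """Lower/upper quartile membership of baseline entry counts.

    Membership uses linear-interpolation sample quantiles; a participant
    belongs to the lower stratum if count <= Q1 and to the upper if
    count >= Q3, computed separately within each training group by
    default.  Degenerate strata (Q1 == Q3) are flagged.
    """
    counts = pd.Series(baseline_counts, dtype=float)
    if groups is None or not within_group:
        groups = pd.Series("all", index=counts.index)
    out = pd.DataFrame({"count": counts, "group": pd.Series(groups)})
    out["quartile"] = pd.NA
    out["degenerate"] = False
    for g, sub in out.groupby("group"):
        if len(sub) < 4:
            raise ValueError(f"stratum {g!r} has fewer than 4 participants")
        q1, q3 = np.quantile(sub["count"], [0.25, 0.75])
        if q1 == q3:
            out.loc[sub.index, "degenerate"] = True
            continue
        out.loc[sub.index[sub["count"] <= q1], "quartile"] = "lower"
        out.loc[sub.index[sub["count"] >= q3], "quartile"] = "upper"
    return out


def entries_under_manipulation(log: ParticipantLog,
                               schedule: GroupSchedule) -> dict[str, int]:
    """Post-message entry counts on the three main manipulation days.

    Counts entries after the manipulation message (daily ordinal beyond
    the message entry) on the devaluation day and the control days
    immediately before and after it.
    """
    dev_day = schedule.devaluation_day
    days = {"control_pre": dev_day - 1, "devaluation": dev_day,
            "control_post": dev_day + 1}
    counts = {k: 0 for k in days}
    for ev in log.events:
        for label, day in days.items():
            if ev.day_index == day and ev.phase.value == "under_manipulation":
                counts[label] += 1
    return counts


def count_dataset(logs: Iterable[ParticipantLog]) -> pd.DataFrame:
    """Long-format dataset for the confirmatory count regression.

    One row per participant x manipulation level with the number of
    entries under manipulation; reference levels are control_pre and the
    short training group.
    """
    rows = []
    for log in logs:
        schedule = schedule_for_group(log.group)
        counts = entries_under_manipulation(log, schedule)
        for manip, n in counts.items():
            rows.append({"participant_id": log.participant_id,
                         "group": log.group, "manipulation": manip,
                         "entries": int(n)})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no participant logs supplied")
    return df


def metrics_table(logs: Iterable[ParticipantLog],
                  config: Optional[TaskConfig] = None) -> pd.DataFrame:
    """One row per participant: adaptation index, engagement indices,
    inclusion flag and manipulation-day counts."""
    rows = []
    for log in logs:
        schedule = schedule_for_group(log.group)
        manip = entries_under_manipulation(log, schedule)
        row = {"participant_id": log.participant_id, "group": log.group,
               **{f"entries_{k}": v for k, v in manip.items()}}
        try:
            idx = adaptation_index(manip["control_pre"], manip["control_post"],
                                   manip["devaluation"])
            row["adaptation_index"] = idx.value
        except ValueError:
            row["adaptation_index"] = float("nan")
        row.update(engagement_indices(log, schedule))
        row.update(exclusion_filter(log, schedule, config))
        rows.append(row)
    return pd.DataFrame(rows)
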