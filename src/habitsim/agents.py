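"""Synthetic participants for the free-operant habit-induction task.

Real participants engage in self-initiated micro-sessions: bursts of
entries separated by long gaps, with heavy between-participant
dispersion in daily entry counts.  The generator reproduces that
structure with a three-level process — a Poisson number of sessions per
day, session onsets uniform in a waking window, and a shifted
negative-binomial number of entries per session with short within-session
gaps — and expresses habit strength through a devaluation-sensitivity
parameter ``s``: after the devaluation message, each further entry the
agent would have made survives with probability ``1 - s``.  ``s = 1`` is
a fully goal-directed agent (stops entirely), ``s = 0`` a fully habitual
one (unchanged rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .task_engine import (
    CaveResult,
    EntryEvent,
    GroupSchedule,
    Manipulation,
    ParticipantState,
    TaskConfig,
    generate_cave_layout,
    process_entry,
    run_cave,
    SECONDS_PER_DAY,
)

__all__ = ["AgentParams", "ParticipantLog", "CohortSpec",
           "simulate_participant", "simulate_cohort", "default_cohort_spec"]


@dataclass
class AgentParams:
    """Generative parameters of one synthetic participant.

    Defaults are calibrated so that a heterogeneous cohort (see
    ``default_cohort_spec``) reproduces the engagement scale observed in
    the study population: a heavy-tailed daily entry distribution with a
    median of roughly 50 entries/day and a mean more than twice that.
    """

    sessions_per_day: float = 6.7
    entries_per_session_mean: float = 8.0
    entries_per_session_dispersion: float = 2.0   # NB shape k; smaller = wider
    within_session_gap_low: float = 10.0          # seconds
    within_session_gap_high: float = 60.0         # strictly below 300 s
    session_window: tuple[float, float] = (8.0, 23.0)   # waking hours
    devaluation_sensitivity: float = 0.9
    control_sensitivity: float = 0.0
    cave_pile_press_prob_valued: float = 0.6
    cave_pile_press_prob_devalued: float = 0.1
    day_drift: float = 1.0
    comply_minimum: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.devaluation_sensitivity <= 1.0:
            raise ValueError("devaluation_sensitivity must lie in [0, 1]")
        if not 0.0 <= self.control_sensitivity <= 1.0:
            raise ValueError("control_sensitivity must lie in [0, 1]")
        if self.sessions_per_day <= 0:
            raise ValueError("sessions_per_day must be positive")
        if self.entries_per_session_mean < 1.0:
            raise ValueError("entries_per_session_mean must be >= 1")
        if not (0 < self.within_session_gap_low
                <= self.within_session_gap_high < 300.0):
            raise ValueError("within-session gaps must lie in (0, 300) seconds")
        lo, hi = self.session_window
        if not (0.0 <= lo < hi <= 24.0):
            raise ValueError("session_window must be within a day")


@dataclass
class ParticipantLog:
    participant_id: str
    group: str
    params: AgentParams
    events: list[EntryEvent]
    cave_results: dict[int, CaveResult] = field(default_factory=dict)
    seed: Optional[int] = None

    def daily_counts(self, n_days: int) -> np.ndarray:
        counts = np.zeros(n_days, dtype=int)
        for ev in self.events:
            counts[ev.day_index - 1] += 1
        return counts

    def timestamps(self) -> np.ndarray:
        return np.array([ev.timestamp for ev in self.events], dtype=float)


def _session_sizes(n_sessions: int, params: AgentParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Shifted negative-binomial entries per session (support >= 1)."""
    m = params.entries_per_session_mean - 1.0
    k = params.entries_per_session_dispersion
    if m <= 0:
        return np.ones(n_sessions, dtype=int)
    p = k / (k + m)
    return 1 + rng.negative_binomial(k, p, size=n_sessions)


def _planned_day_timestamps(day: int, params: AgentParams, intensity_scale: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Candidate entry timestamps for one experiment day (seconds)."""
    rate = params.sessions_per_day * intensity_scale
    n_sessions = rng.poisson(rate)
    if params.comply_minimum:
        n_sessions = max(n_sessions, 1)
    if n_sessions == 0:
        return np.empty(0)
    lo, hi = params.session_window
    day_start = (day - 1) * SECONDS_PER_DAY
    starts = np.sort(day_start + rng.uniform(lo, hi, size=n_sessions) * 3600.0)
    sizes = _session_sizes(n_sessions, params, rng)
    stamps = []
    for start, size in zip(starts, sizes):
        gaps = rng.uniform(params.within_session_gap_low,
                           params.within_session_gap_high, size=size - 1)
        stamps.append(start + np.concatenate([[0.0], np.cumsum(gaps)]))
    ts = np.concatenate(stamps)
    return np.sort(ts)


def _pad_to_minimum(ts: np.ndarray, day: int, params: AgentParams,
                    minimum: int, rng: np.random.Generator) -> np.ndarray:
    """Append extra within-session entries until the compliance floor holds."""
    if ts.size >= minimum:
        return ts
    anchor = ts[-1] if ts.size else ((day - 1) * SECONDS_PER_DAY
                                     + params.session_window[0] * 3600.0)
    extra = rng.uniform(params.within_session_gap_low,
                        params.within_session_gap_high,
                        size=minimum - ts.size)
    return np.concatenate([ts, anchor + np.cumsum(extra)])


def simulate_participant(params: AgentParams, schedule: GroupSchedule,
                         config: TaskConfig, seed: int,
                         participant_id: Optional[str] = None) -> ParticipantLog:
    """Simulate one participant's full event log through the task engine.

    On manipulation days the entries an agent would have made after the
    warehouse message are independently thinned with probability ``s``
    (devaluation) or ``control_sensitivity`` (control), so the expected
    post-manipulation count is ``(1 - s)`` times the matched valued-day
    expectation.
    """
    rng = np.random.default_rng(seed)
    pid = participant_id or f"{schedule.group.value}_{seed}"
    state = ParticipantState(participant_id=pid)
    events: list[EntryEvent] = []
    caves: dict[int, CaveResult] = {}

    for day in range(1, schedule.n_days + 1):
        scale = params.day_drift ** (day - 1)
        ts = _planned_day_timestamps(day, params, scale, rng)
        if params.comply_minimum:
            ts = _pad_to_minimum(ts, day, params, config.min_daily_entries, rng)
        manip = (schedule.manipulation_on(day)
                 if config.manipulations_enabled else Manipulation.NONE)
        sens = {Manipulation.DEVALUATION: params.devaluation_sensitivity,
                Manipulation.CONTROL: params.control_sensitivity}.get(manip, 0.0)
        ordinal = 0
        for t in ts:
            ordinal += 1
            if (manip is not Manipulation.NONE
                    and ordinal > config.manipulation_entry
                    and rng.random() < sens):
                continue    # devaluation-sensitive agent withholds this entry
            ev = process_entry(state, float(t), config, schedule, rng)
            events.append(ev)
            if (ev.manipulation_shown is not Manipulation.NONE
                    and ev.daily_ordinal == config.manipulation_entry
                    and config.manipulation_check_mode == "cave"):
                caves[day] = _play_cave(state, params, config, rng)
    return ParticipantLog(participant_id=pid, group=schedule.group.value,
                          params=params, events=events, cave_results=caves,
                          seed=seed)


def _play_cave(state: ParticipantState, params: AgentParams, config: TaskConfig,
               rng: np.random.Generator) -> CaveResult:
    layout = generate_cave_layout(config, rng)
    p = (params.cave_pile_press_prob_valued if state.warehouse.valued
         else params.cave_pile_press_prob_devalued)
    n_press = rng.binomial(config.cave_n_piles, p)
    targets = ["pile"] * int(n_press)
    return run_cave(state.warehouse, targets, config, rng)


@dataclass
class CohortSpec:
    """Population description for a simulated cohort.

    ``intensity_lognorm_sigma`` spreads a per-participant multiplier on
    session rate, producing the strong between-participant overdispersion
    in daily counts that motivates negative-binomial modelling.
    ``habitual_fraction``/``habitual_sensitivity`` define an optional
    low-sensitivity latent subgroup (by default only in the extensive
    training groups), mirroring a two-cluster population.
    """

    n_per_group: dict[str, int]
    base_params: AgentParams = field(default_factory=AgentParams)
    intensity_lognorm_sigma: float = 1.284
    habitual_fraction: dict[str, float] = field(default_factory=dict)
    habitual_sensitivity: float = 0.1

    def __post_init__(self) -> None:
        if not self.n_per_group:
            raise ValueError("n_per_group must not be empty")
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"n_per_group[{g!r}] must be >= 1")


def default_cohort_spec(n_per_group: int = 45,
                        habitual: bool = True) -> CohortSpec:
    """Study-scale cohort: 45 per group, habitual subgroup (half) in the
    extensive training groups only."""
    frac = {"extensive": 0.5, "extensive_parallel": 0.5} if habitual else {}
    return CohortSpec(
        n_per_group={g: n_per_group for g in
                     ("short", "extensive", "extensive_parallel")},
        habitual_fraction=frac,
    )


def simulate_cohort(spec: CohortSpec, config: TaskConfig,
                    master_seed: int) -> list[ParticipantLog]:
    """Simulate every participant in the cohort, reproducibly.

    Per-participant seeds are drawn from a generator seeded by
    ``master_seed``; per-participant intensity multipliers are lognormal
    and habitual-subgroup membership is Bernoulli with the per-group
    fraction from the cohort specification.
    """
    rng = np.random.default_rng(master_seed)
    logs: list[ParticipantLog] = []
    for group, n in spec.n_per_group.items():
        schedule_seed_base = rng.integers(0, 2**31 - 1)
        from .task_engine import schedule_for_group
        schedule = schedule_for_group(group)
        for i in range(n):
            # median-preserving lognormal multiplier: the median participant
            # keeps the base rate while the mean sits well above it
            mult = float(np.exp(rng.normal(0.0, spec.intensity_lognorm_sigma)))
            params = replace(spec.base_params,
                             sessions_per_day=spec.base_params.sessions_per_day * mult)
            if rng.random() < spec.habitual_fraction.get(group, 0.0):
                params = replace(params,
                                 devaluation_sensitivity=spec.habitual_sensitivity)
            seed = int((schedule_seed_base + 7919 * i) % (2**31 - 1))
            logs.append(simulate_participant(
                params, schedule, config, seed,
                participant_id=f"{group}_{i:03d}"))
    return logs
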