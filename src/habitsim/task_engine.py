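"""State machine for the gold-planet real-world free-operant task.

Participants freely enter a gamified app to dig for gold on a
variable-ratio reinforcement schedule.  Each entry costs one gold unit and
yields either a 15-unit gold pile or a worthless rock.  On scheduled
manipulation days the warehouse that stores the gold becomes full
(outcome devaluation — further gold is worthless for the rest of the day)
or half full (control — the outcome keeps its value), announced on the
fifth daily entry; outcomes are masked from the third daily entry onward
on those days.  Entries committed after the announcement are the
behavioural dependent variable for habit analyses.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "TaskConfig",
    "GroupSchedule",
    "Group",
    "Manipulation",
    "Outcome",
    "WarehouseStatus",
    "WarehouseState",
    "EntryEvent",
    "CaveResult",
    "ParticipantState",
    "schedule_for_group",
    "draw_outcome",
    "process_entry",
    "run_cave",
]

SECONDS_PER_DAY = 86_400.0


class Outcome(str, enum.Enum):
    GOLD = "gold"
    ROCK = "rock"


class Manipulation(str, enum.Enum):
    NONE = "none"
    CONTROL = "control"
    DEVALUATION = "devaluation"


class Group(str, enum.Enum):
    SHORT = "short"
    EXTENSIVE = "extensive"
    EXTENSIVE_PARALLEL = "extensive_parallel"


class WarehouseStatus(str, enum.Enum):
    EMPTY_START = "empty_start"
    HALF_FULL = "half_full"
    FULL = "full"


class Phase(str, enum.Enum):
    PRE_MANIPULATION = "pre_manipulation"
    UNDER_MANIPULATION = "under_manipulation"


class ScheduleKind(str, enum.Enum):
    RATIO = "ratio"
    RANDOM_INTERVAL = "random_interval"


@dataclass
class TaskConfig:
    """Every tunable parameter of the paradigm.

    Defaults reproduce the published study: 1-unit entry cost, 15-unit
    reward with probability 1/3 (VR-3), gold guaranteed after six
    consecutive failures, first daily entry forced to rock and second to
    gold, outcome masking from the third daily entry on manipulation
    days, warehouse message on the fifth, compliance floor of five daily
    entries, day boundary at 05:00, and a 5-second cave mini-task with
    15 gold piles and 15 rocks at a 10-unit press cost.
    """

    entry_cost: float = 1.0
    reward_magnitude: float = 15.0
    reward_probability: float = 1.0 / 3.0
    guarantee_after_failures: int = 6
    fixed_daily_pattern: bool = True
    masking_start_entry: int = 3
    manipulation_entry: int = 5
    min_daily_entries: int = 5
    day_boundary_hour: float = 5.0
    cave_duration: float = 5.0
    cave_press_cost: float = 10.0
    cave_pile_value: float = 15.0
    cave_n_piles: int = 15
    cave_n_rocks: int = 15
    manipulation_check_mode: str = "cave"
    devaluation_reminder: bool = False
    schedule_kind: ScheduleKind = ScheduleKind.RATIO
    random_interval_mean: float = 600.0
    aversive_outcomes: bool = False
    aversive_magnitude: float = 0.0
    manipulations_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.reward_probability <= 1.0:
            raise ValueError("reward_probability must lie in [0, 1]")
        for name in ("entry_cost", "reward_magnitude", "cave_press_cost",
                     "cave_pile_value", "aversive_magnitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.masking_start_entry >= self.manipulation_entry:
            raise ValueError("masking_start_entry must precede manipulation_entry")
        if self.guarantee_after_failures < 1:
            raise ValueError("guarantee_after_failures must be >= 1")
        if isinstance(self.schedule_kind, str):
            self.schedule_kind = ScheduleKind(self.schedule_kind)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schedule_kind"] = self.schedule_kind.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown TaskConfig fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroupSchedule:
    """Training-duration group: number of days and manipulation calendar."""

    group: Group
    n_days: int
    manipulation_calendar: dict[int, Manipulation]

    @property
    def devaluation_day(self) -> int:
        for day, manip in self.manipulation_calendar.items():
            if manip is Manipulation.DEVALUATION:
                return day
        raise ValueError("schedule has no devaluation day")

    def manipulation_on(self, day_index: int) -> Manipulation:
        return self.manipulation_calendar.get(day_index, Manipulation.NONE)


def schedule_for_group(group: Group | str) -> GroupSchedule:
    """Return the published manipulation calendar for a training group.

    Short training lasts 4 days with control/devaluation/control on days
    2-4; extensive training lasts 11 days with the same triad on days
    9-11; the parallel-manipulations variant adds controls on days 2-4.
    """
    group = Group(group)
    if group is Group.SHORT:
        cal = {2: Manipulation.CONTROL, 3: Manipulation.DEVALUATION,
               4: Manipulation.CONTROL}
        return GroupSchedule(group, 4, cal)
    cal = {9: Manipulation.CONTROL, 10: Manipulation.DEVALUATION,
           11: Manipulation.CONTROL}
    if group is Group.EXTENSIVE:
        return GroupSchedule(group, 11, cal)
    cal = {2: Manipulation.CONTROL, 3: Manipulation.CONTROL,
           4: Manipulation.CONTROL, **cal}
    return GroupSchedule(group, 11, cal)


@dataclass
class WarehouseState:
    day_index: int = 1
    status: WarehouseStatus = WarehouseStatus.EMPTY_START
    gold_today: float = 0.0
    message_pending: bool = False

    @property
    def valued(self) -> bool:
        return self.status is not WarehouseStatus.FULL


@dataclass
class EntryEvent:
    participant_id: str
    timestamp: float
    day_index: int
    daily_ordinal: int
    outcome: Outcome
    masked: bool
    manipulation_shown: Manipulation
    gold_delta: float
    phase: Phase
    sequence_completed: bool = True

    def to_record(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "timestamp": self.timestamp,
            "day_index": self.day_index,
            "daily_ordinal": self.daily_ordinal,
            "outcome": self.outcome.value,
            "masked": self.masked,
            "manipulation_shown": self.manipulation_shown.value,
            "gold_delta": self.gold_delta,
            "phase": self.phase.value,
            "sequence_completed": self.sequence_completed,
        }

    @classmethod
    def from_record(cls, r: dict) -> "EntryEvent":
        return cls(
            participant_id=str(r["participant_id"]),
            timestamp=float(r["timestamp"]),
            day_index=int(r["day_index"]),
            daily_ordinal=int(r["daily_ordinal"]),
            outcome=Outcome(r["outcome"]),
            masked=_as_bool(r["masked"]),
            manipulation_shown=Manipulation(r["manipulation_shown"]),
            gold_delta=float(r["gold_delta"]),
            phase=Phase(r["phase"]),
            sequence_completed=_as_bool(r.get("sequence_completed", True)),
        )


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"true", "1", "t", "yes"}
    return bool(x)


@dataclass
class CaveResult:
    presses: int
    piles_collected: int
    gold_delta: float
    warehouse_valued: bool


@dataclass
class ParticipantState:
    """Mutable per-participant simulation state threaded through entries."""

    participant_id: str
    day_index: int = 0           # 0 until the first entry
    daily_ordinal: int = 0
    failure_streak: int = 0
    warehouse: WarehouseState = field(default_factory=WarehouseState)
    last_timestamp: float = -np.inf
    gold_total: float = 0.0
    manipulation_confirmed: bool = False
    reward_available: bool = False       # random-interval schedule
    next_reward_time: float = np.inf


def day_index_for(timestamp: float, config: TaskConfig) -> int:
    """Experiment day for a timestamp in seconds since experiment start.

    Time 0 is midnight before the first day; the day boundary (default
    05:00) separates experiment days, so an entry at 02:00 still belongs
    to the previous experiment day.
    """
    boundary = config.day_boundary_hour * 3600.0
    return int(np.floor((timestamp - boundary) / SECONDS_PER_DAY)) + 1


def draw_outcome(daily_ordinal: int, failure_streak: int, config: TaskConfig,
                 rng: np.random.Generator) -> Outcome:
    """Draw a single entry outcome under the VR schedule.

    The fixed daily pattern forces ordinal 1 to rock and ordinal 2 to
    gold; after ``guarantee_after_failures`` consecutive rocks the next
    entry is guaranteed gold; otherwise the outcome is
    Bernoulli(reward_probability).
    """
    if daily_ordinal < 1:
        raise ValueError("daily_ordinal must be >= 1")
    if failure_streak < 0:
        raise ValueError("failure_streak must be >= 0")
    if config.fixed_daily_pattern:
        if daily_ordinal == 1:
            return Outcome.ROCK
        if daily_ordinal == 2:
            return Outcome.GOLD
    if failure_streak >= config.guarantee_after_failures:
        return Outcome.GOLD
    return Outcome.GOLD if rng.random() < config.reward_probability else Outcome.ROCK


def _begin_day(state: ParticipantState, day: int) -> None:
    state.day_index = day
    state.daily_ordinal = 0
    # cargo spaceship empties the warehouse every morning
    state.warehouse = WarehouseState(day_index=day)
    state.manipulation_confirmed = False


def process_entry(state: ParticipantState, timestamp: float, config: TaskConfig,
                  schedule: GroupSchedule, rng: np.random.Generator,
                  confirm_message: bool = True) -> EntryEvent:
    """Process one app entry, mutating ``state`` and returning the event.

    Handles day rollover (warehouse reset), the entry cost, the VR
    outcome draw, outcome masking, the warehouse manipulation message at
    the configured ordinal (with re-display until confirmed), and reward
    crediting only while the warehouse is valued.
    """
    if timestamp < state.last_timestamp:
        raise ValueError(
            f"out-of-order timestamp {timestamp} for {state.participant_id}")
    day = day_index_for(timestamp, config)
    if day < 1:
        raise ValueError("entry precedes the first experiment day")
    if day > schedule.n_days:
        raise ValueError(f"entry on day {day} beyond n_days={schedule.n_days}")
    if day != state.day_index:
        _begin_day(state, day)
    state.last_timestamp = timestamp
    state.daily_ordinal += 1
    ordinal = state.daily_ordinal

    manip_today = (schedule.manipulation_on(day)
                   if config.manipulations_enabled else Manipulation.NONE)
    is_manip_day = manip_today is not Manipulation.NONE

    outcome = _draw_entry_outcome(state, timestamp, ordinal, config, rng)

    masked = is_manip_day and ordinal >= config.masking_start_entry

    shown = Manipulation.NONE
    if is_manip_day and ordinal == config.manipulation_entry:
        state.warehouse.status = (WarehouseStatus.FULL
                                  if manip_today is Manipulation.DEVALUATION
                                  else WarehouseStatus.HALF_FULL)
        state.warehouse.message_pending = True
    if state.warehouse.message_pending:
        shown = manip_today
        if confirm_message:
            state.warehouse.message_pending = False
            state.manipulation_confirmed = True

    gold_delta = -config.entry_cost
    if outcome is Outcome.GOLD and state.warehouse.valued:
        gold_delta += config.reward_magnitude
        state.warehouse.gold_today += config.reward_magnitude
    state.gold_total += gold_delta

    phase = Phase.PRE_MANIPULATION
    if (is_manip_day and state.manipulation_confirmed
            and ordinal > config.manipulation_entry):
        phase = Phase.UNDER_MANIPULATION

    return EntryEvent(
        participant_id=state.participant_id,
        timestamp=timestamp,
        day_index=day,
        daily_ordinal=ordinal,
        outcome=outcome,
        masked=masked,
        manipulation_shown=shown,
        gold_delta=gold_delta,
        phase=phase,
    )


def _draw_entry_outcome(state: ParticipantState, timestamp: float, ordinal: int,
                        config: TaskConfig, rng: np.random.Generator) -> Outcome:
    if config.schedule_kind is ScheduleKind.RANDOM_INTERVAL:
        # reward becomes available after an exponential interval and is
        # delivered on the next entry; fixed pattern layered on top
        if config.fixed_daily_pattern and ordinal == 1:
            return Outcome.ROCK
        if config.fixed_daily_pattern and ordinal == 2:
            return Outcome.GOLD
        if timestamp >= state.next_reward_time:
            state.next_reward_time = timestamp + rng.exponential(
                config.random_interval_mean)
            return Outcome.GOLD
        if not np.isfinite(state.next_reward_time):
            state.next_reward_time = timestamp + rng.exponential(
                config.random_interval_mean)
        return Outcome.ROCK
    outcome = draw_outcome(ordinal, state.failure_streak, config, rng)
    if outcome is Outcome.GOLD:
        state.failure_streak = 0
    else:
        state.failure_streak += 1
    return outcome


def generate_cave_layout(config: TaskConfig, rng: np.random.Generator) -> list[str]:
    """Random arrangement of exactly cave_n_piles piles and cave_n_rocks rocks."""
    layout = ["pile"] * config.cave_n_piles + ["rock"] * config.cave_n_rocks
    rng.shuffle(layout)
    return layout


def run_cave(warehouse: WarehouseState, press_targets: list[str],
             config: TaskConfig,
             rng: Optional[np.random.Generator] = None) -> CaveResult:
    """Score a cave mini-task given the sequence of press targets.

    Every press costs ``cave_press_cost``; presses on gold piles credit
    ``cave_pile_value`` each, but only while the warehouse is valued.
    """
    n_pile_presses = sum(1 for t in press_targets if t == "pile")
    if n_pile_presses > config.cave_n_piles:
        raise ValueError("more pile presses than piles in the cave")
    if any(t not in ("pile", "rock") for t in press_targets):
        raise ValueError("press targets must be 'pile' or 'rock'")
    presses = len(press_targets)
    credit = n_pile_presses * config.cave_pile_value if warehouse.valued else 0.0
    gold_delta = credit - presses * config.cave_press_cost
    warehouse.gold_today += credit
    return CaveResult(presses=presses, piles_collected=n_pile_presses,
                      gold_delta=gold_delta, warehouse_valued=warehouse.valued)
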