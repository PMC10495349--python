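"""Agent-based simulator of the dual-feeder social-foraging experiment.

The simulated experiment mirrors a field manipulation in which every bird in a
wild population carries an RFID leg ring and is assigned to one of two
treatment classes, A or B.  Pairs of automated feeders ("apparatus" units,
each with two perches) respond to the class combination of the two occupants:
a same-class dyad unlocks a high-quality reward ("success"), a different-class
dyad triggers a feeder lockout ("fail").  The module provides

* :func:`assign_classes` — the constrained randomization used to allocate
  treatment classes (supervised for known pairs and regular feeder users,
  unsupervised fair coin for everyone else);
* :func:`step_task_state` — the four-state / eight-transition feeder state
  machine;
* :func:`simulate_experiment` — a generative model of visitation and partner
  choice with known ground-truth parameters (class-learning rate ``lam`` and
  affiliate bonus ``theta``), producing per-second visit records and the true
  dyadic event list.

The partner-choice model is deliberately simple: an arriving bird joins an
occupied feeder with probability ``w / (1 + w)`` where
``w = exp(theta * affiliate(i, j) + lam * q_ij)`` and ``q_ij`` is the running
net reward (+1 per success, -1 per fail) the pair has accumulated together.
With ``lam = theta = 0`` partner choice is uniform and the same-class event
fraction converges to the analytic random-mixing expectation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeederState",
    "TaskState",
    "SimConfig",
    "SimResult",
    "REWARD_ACCESS",
    "assign_classes",
    "step_task_state",
    "build_population",
    "simulate_experiment",
    "visits_per_second",
]


class FeederState(enum.Enum):
    DEFAULT = "default"
    LOCKOUT = "lockout"
    SUCCESS = "success"
    SUCCESS_OVERRIDE = "success_override"


#: Reward accessibility (low-quality, high-quality) as a function of state only.
REWARD_ACCESS: dict[FeederState, tuple[bool, bool]] = {
    FeederState.DEFAULT: (True, False),
    FeederState.LOCKOUT: (False, False),
    FeederState.SUCCESS: (True, True),
    FeederState.SUCCESS_OVERRIDE: (False, True),
}

_OCCUPANCIES = ("empty", "solo", "dyad")


@dataclass(frozen=True)
class TaskState:
    """State of one feeder unit.

    ``lockout_remaining`` is only positive in LOCKOUT or SUCCESS_OVERRIDE;
    ``success_elapsed`` tracks seconds since the onset of the current
    successful dyadic event (used for the minimum-access window).
    """

    state: FeederState = FeederState.DEFAULT
    lockout_remaining: float = 0.0
    success_elapsed: float = 0.0

    def __post_init__(self) -> None:
        if self.lockout_remaining < 0 or self.success_elapsed < 0:
            raise ValueError("timers must be non-negative")
        if self.lockout_remaining > 0 and self.state not in (
            FeederState.LOCKOUT,
            FeederState.SUCCESS_OVERRIDE,
        ):
            raise ValueError(
                "lockout_remaining > 0 only valid in LOCKOUT/SUCCESS_OVERRIDE"
            )

    @property
    def low_reward_accessible(self) -> bool:
        return REWARD_ACCESS[self.state][0]

    @property
    def high_reward_accessible(self) -> bool:
        return REWARD_ACCESS[self.state][1]


def step_task_state(
    task: TaskState,
    occupancy: str,
    class_match: bool,
    dt: float,
    *,
    lockout_duration: float = 120.0,
    min_success_access: float = 15.0,
) -> TaskState:
    """Advance the feeder state machine.

    Semantics: ``dt`` seconds elapse in the current state (timers run and may
    expire), after which the new ``occupancy`` observation is applied.  The
    eight transitions:

    1. default + unsuccessful dyad -> lockout (timer = ``lockout_duration``)
    2. lockout timer expiry -> default
    3. default + successful dyad -> success (both rewards)
    4. end of success outside lockout -> default
    5. lockout + successful dyad -> success-override (high-quality only)
    6. success-override ends before lockout expiry -> back to lockout
    7. lockout expiry during ongoing success -> success (both rewards)
    8. unsuccessful dyad immediately after a success -> lockout directly

    An unsuccessful dyad during an active lockout restarts the full timer.
    The high-quality reward, once opened, stays open for at least
    ``min_success_access`` seconds from event onset even if the dyad leaves
    earlier.
    """
    if occupancy not in _OCCUPANCIES:
        raise ValueError(f"unknown occupancy {occupancy!r}")
    if dt <= 0:
        raise ValueError("dt must be positive")

    state = task.state
    lock = task.lockout_remaining
    succ = task.success_elapsed

    # --- phase 1: dt elapses in the current state ---------------------------
    if state is FeederState.LOCKOUT:
        lock = max(0.0, lock - dt)
        if lock == 0.0:
            state = FeederState.DEFAULT  # (2)
    elif state is FeederState.SUCCESS_OVERRIDE:
        lock = max(0.0, lock - dt)
        succ += dt
        if lock == 0.0:
            state = FeederState.SUCCESS  # (7)
    elif state is FeederState.SUCCESS:
        succ += dt

    # --- phase 2: apply the occupancy observation ---------------------------
    if occupancy == "dyad":
        if class_match:
            if state is FeederState.DEFAULT:
                state, succ = FeederState.SUCCESS, 0.0  # (3)
            elif state is FeederState.LOCKOUT:
                state, succ = FeederState.SUCCESS_OVERRIDE, 0.0  # (5)
            # ongoing SUCCESS / SUCCESS_OVERRIDE persists
        else:
            # (1), (8) and lockout restarts all funnel here
            state, lock, succ = FeederState.LOCKOUT, lockout_duration, 0.0
    else:  # empty or solo: any dyadic event has ended
        if state is FeederState.SUCCESS and succ >= min_success_access:
            state, succ = FeederState.DEFAULT, 0.0  # (4)
        elif state is FeederState.SUCCESS_OVERRIDE and succ >= min_success_access:
            state, succ = FeederState.LOCKOUT, 0.0  # (6)
        # below the minimum-access window the reward stays open

    if state not in (FeederState.LOCKOUT, FeederState.SUCCESS_OVERRIDE):
        lock = 0.0
    if state not in (FeederState.SUCCESS, FeederState.SUCCESS_OVERRIDE):
        succ = 0.0
    return TaskState(state, lock, succ)


# ---------------------------------------------------------------------------
# treatment-class assignment
# ---------------------------------------------------------------------------


def assign_classes(
    individuals: Sequence[str],
    pair_list: Sequence[tuple[str, str]],
    regular_list: Sequence[str],
    rng: np.random.Generator,
) -> dict[str, str]:
    """Constrained randomization of treatment classes.

    Known pairs are assigned so that exactly half (rounded down) are
    same-class — AA and BB in equal numbers where possible — and the rest
    different-class.  Regular feeder users without a known partner are split
    equally between classes.  Everyone else gets an independent fair coin.
    """
    individuals = list(individuals)
    seen: set[str] = set()
    for a, b in pair_list:
        for m in (a, b):
            if m in seen:
                raise ValueError(f"individual {m!r} appears in more than one pair")
            seen.add(m)
    if a_dup := (set(regular_list) & seen):
        raise ValueError(f"regulars overlap pair members: {sorted(a_dup)}")
    if len(set(regular_list)) != len(regular_list):
        raise ValueError("duplicate individual in regular_list")

    classes: dict[str, str] = {}

    n_pairs = len(pair_list)
    n_same = n_pairs // 2
    order = rng.permutation(n_pairs)
    n_aa = n_same // 2
    if n_same % 2:
        n_aa += int(rng.integers(2))  # odd count: coin decides the extra
    for rank, idx in enumerate(order):
        a, b = pair_list[idx]
        if rank < n_same:
            label = "A" if rank < n_aa else "B"
            classes[a] = classes[b] = label
        else:
            first_a = bool(rng.integers(2))
            classes[a] = "A" if first_a else "B"
            classes[b] = "B" if first_a else "A"

    regs = list(regular_list)
    reg_order = rng.permutation(len(regs))
    n_reg_a = len(regs) // 2
    if len(regs) % 2:
        n_reg_a += int(rng.integers(2))
    for rank, idx in enumerate(reg_order):
        classes[regs[idx]] = "A" if rank < n_reg_a else "B"

    for ind in individuals:
        if ind not in classes:
            classes[ind] = "A" if rng.integers(2) else "B"
    return classes


# ---------------------------------------------------------------------------
# simulation configuration and population
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults emulate the field study's scale: ~140 tagged individuals, two
    apparatus units run for four hours on each of ~85 mornings, with known
    mated pairs, sibling broods that enter mid-experiment as fledged
    juveniles, and parent-offspring affiliations.
    """

    seed: int
    n_individuals: int = 140
    n_mate_pairs: int = 20
    n_sibling_groups: int = 10
    n_parent_offspring_links: int = 20
    n_days: int = 85
    n_feeders: int = 2
    session_length: int = 14400
    arrival_rate: float = 0.9
    mean_visit_duration: float = 60.0
    learning_rate: float = 0.25
    affiliate_weight: float = 3.0
    affiliate_co_arrival: float = 0.15
    rate_heterogeneity: float = 0.5
    site_fidelity: float = 0.85
    min_success_access: float = 15.0
    lockout_duration: float = 120.0
    brood_size: int = 2
    juvenile_entry_day: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "n_individuals",
            "n_days",
            "n_feeders",
            "session_length",
            "brood_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_mate_pairs", "n_sibling_groups", "n_parent_offspring_links"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.arrival_rate < 0 or self.mean_visit_duration < 1:
            raise ValueError("invalid arrival/visit parameters")
        if not 0 <= self.affiliate_co_arrival <= 1:
            raise ValueError("affiliate_co_arrival must be a probability")
        if self.rate_heterogeneity <= 0:
            raise ValueError("rate_heterogeneity must be positive")
        if not 0 < self.site_fidelity <= 1:
            raise ValueError("site_fidelity must lie in (0, 1]")
        n_juv = self.n_sibling_groups * self.brood_size
        n_adults = self.n_individuals - n_juv
        if n_adults < 2 * self.n_mate_pairs:
            raise ValueError("not enough adults for the requested mate pairs")
        if self.n_parent_offspring_links > n_juv * 2:
            raise ValueError("too many parent-offspring links for the juveniles")
        if self.n_parent_offspring_links and self.n_sibling_groups > self.n_mate_pairs:
            # parents are drawn from mate pairs; broods beyond the pair count
            # would have no identified parents
            if self.n_parent_offspring_links > 0 and self.n_mate_pairs == 0:
                raise ValueError("parent-offspring links require mate pairs")

    @property
    def entry_day(self) -> int:
        day = (
            self.juvenile_entry_day
            if self.juvenile_entry_day is not None
            else self.n_days // 2
        )
        return min(day, self.n_days - 1) if self.n_days > 1 else 0


@dataclass
class SimResult:
    """Output bundle of :func:`simulate_experiment`."""

    individuals: pd.DataFrame
    affiliations: pd.DataFrame
    visits: pd.DataFrame  # interval form: tag_id, day, feeder, perch, start, end
    events: pd.DataFrame
    config: SimConfig = field(repr=False)

    def class_map(self) -> dict[str, str]:
        return dict(zip(self.individuals["id"], self.individuals["treatment_class"]))

    def affiliate_pairs(self) -> set[frozenset]:
        return {
            frozenset((a, b))
            for a, b in zip(self.affiliations["id1"], self.affiliations["id2"])
        }


def build_population(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Create individuals and affiliation edges for one simulated colony.

    Adults are present from day 0; sibling broods are fledged juveniles that
    first appear on ``entry_day``.  Mate pairs are adults; each brood's
    parents are the members of the matching mate pair, so parent-offspring
    edges attach juveniles to those adults.  Affiliation relations are
    symmetric and each individual has at most one mate.
    """
    n_juv = config.n_sibling_groups * config.brood_size
    n_adults = config.n_individuals - n_juv
    ids = [f"J{i:03d}" for i in range(config.n_individuals)]
    adults, juveniles = ids[:n_adults], ids[n_adults:]

    pairs = [(adults[2 * k], adults[2 * k + 1]) for k in range(config.n_mate_pairs)]
    paired = {m for p in pairs for m in p}
    regulars = [a for a in adults if a not in paired]

    edges: list[tuple[str, str, str]] = [(a, b, "mate") for a, b in pairs]
    broods = [
        juveniles[g * config.brood_size : (g + 1) * config.brood_size]
        for g in range(config.n_sibling_groups)
    ]
    for brood in broods:
        for i in range(len(brood)):
            for j in range(i + 1, len(brood)):
                edges.append((brood[i], brood[j], "sibling"))
    po_left = config.n_parent_offspring_links
    for g, brood in enumerate(broods):
        if po_left <= 0:
            break
        if g >= len(pairs):
            break
        for child in brood:
            for parent in pairs[g]:
                if po_left <= 0:
                    break
                edges.append((parent, child, "parent_offspring"))
                po_left -= 1
    if po_left > 0:
        raise ValueError(
            "could not place all parent-offspring links; "
            "increase n_mate_pairs or n_sibling_groups"
        )

    classes = assign_classes(ids, pairs, regulars, rng)
    entry = {i: (config.entry_day if i in set(juveniles) else 0) for i in ids}
    individuals = pd.DataFrame(
        {
            "id": ids,
            "treatment_class": [classes[i] for i in ids],
            "entry_day": [entry[i] for i in ids],
            "is_regular": [i in set(regulars) for i in ids],
        }
    )
    affiliations = pd.DataFrame(edges, columns=["id1", "id2", "relation"])
    return individuals, affiliations


# ---------------------------------------------------------------------------
# the experiment itself
# ---------------------------------------------------------------------------


def _join_weight(
    i: str,
    j: str,
    q: Mapping[tuple[str, str], float],
    affiliates: set[frozenset],
    config: SimConfig,
) -> float:
    key = (i, j) if i < j else (j, i)
    w = config.learning_rate * q.get(key, 0.0)
    if frozenset((i, j)) in affiliates:
        w += config.affiliate_weight
    return float(np.exp(w))


def simulate_experiment(config: SimConfig) -> SimResult:
    """Run the full synthetic experiment.

    Each day, every individual already present in the population draws a
    Poisson number of visit intents per feeder (rate ``arrival_rate``), at
    uniform times within the session, with geometric visit durations (mean
    ``mean_visit_duration`` seconds).  Arrivals across the day's feeders are
    processed in strict time order so that within-day learning at one feeder
    influences choices at the other.  An arriving bird occupies a free feeder
    alone, joins a solo occupant with the softmax probability described in
    the module docstring, or moves on if both perches are taken.

    Returns per-second-equivalent visit intervals, the ground-truth ordered
    event list, and the population tables.  The event list is exactly what
    :func:`premnet.events.extract_events` recovers from the visit records
    (with ``gap_tolerance=0``).
    """
    rng = np.random.default_rng(config.seed)
    individuals, affiliations = build_population(config, rng)
    class_of = dict(zip(individuals["id"], individuals["treatment_class"]))
    entry_of = dict(zip(individuals["id"], individuals["entry_day"]))
    affiliates = {
        frozenset((a, b)) for a, b in zip(affiliations["id1"], affiliations["id2"])
    }

    q: dict[tuple[str, str], float] = {}
    visit_rows: list[tuple] = []
    event_rows: list[tuple] = []

    ids = list(individuals["id"])
    partners_of: dict[str, list[str]] = {i: [] for i in ids}
    for a, b in zip(affiliations["id1"], affiliations["id2"]):
        partners_of[a].append(b)
        partners_of[b].append(a)

    # fission-fusion realism: individuals differ in visitation propensity
    # (gamma multipliers, mean 1) and favour one apparatus over the other
    shape = config.rate_heterogeneity
    rate_mult = {i: rng.gamma(shape, 1.0 / shape) for i in ids}
    preferred = {i: int(rng.integers(config.n_feeders)) for i in ids}
    if config.n_feeders > 1:
        other_share = (1.0 - config.site_fidelity) / (config.n_feeders - 1)
    else:
        other_share = 0.0

    for day in range(config.n_days):
        present = [i for i in ids if entry_of[i] <= day]
        present_set = set(present)
        arrivals: list[tuple[int, float, str, int, int]] = []
        # deterministic order: individuals then feeders, one rng stream
        for ind in present:
            total = config.arrival_rate * config.n_feeders * rate_mult[ind]
            for feeder in range(config.n_feeders):
                share = (
                    config.site_fidelity
                    if feeder == preferred[ind] or config.n_feeders == 1
                    else other_share
                )
                n_vis = rng.poisson(total * share)
                for _ in range(n_vis):
                    t = int(rng.integers(0, config.session_length))
                    dur = int(rng.geometric(1.0 / config.mean_visit_duration))
                    arrivals.append((t, rng.random(), ind, feeder, dur))
                    # affiliates travel together: each partner may turn up
                    # at the same feeder moments later
                    for p in partners_of[ind]:
                        if p in present_set and (
                            rng.random() < config.affiliate_co_arrival
                        ):
                            t_p = t + int(rng.integers(1, 8))
                            dur_p = int(
                                rng.geometric(1.0 / config.mean_visit_duration)
                            )
                            if t_p < config.session_length:
                                arrivals.append(
                                    (t_p, rng.random(), p, feeder, dur_p)
                                )
        arrivals.sort()  # time, then random tie-break

        # perch occupancy per feeder: {perch: (tag, arrival, departure)}
        occ: list[dict[int, tuple[str, int, int]]] = [
            {} for _ in range(config.n_feeders)
        ]
        busy_until: dict[str, int] = {}
        for t, _tie, ind, feeder, dur in arrivals:
            slots = occ[feeder]
            for perch in list(slots):
                if slots[perch][2] <= t:
                    del slots[perch]
            if busy_until.get(ind, -1) >= t:
                continue  # already perched somewhere (or leaving this second)
            departure = min(t + dur, config.session_length)
            if departure <= t:
                continue
            if not slots:
                slots[0] = (ind, t, departure)
                busy_until[ind] = departure
                visit_rows.append((ind, day, feeder, 0, t, departure))
            elif len(slots) == 1:
                (perch_j,) = slots
                j, t_j, dep_j = slots[perch_j]
                w = _join_weight(ind, j, q, affiliates, config)
                if rng.random() >= w / (1.0 + w):
                    continue  # declines to join; forages elsewhere
                perch_i = 1 - perch_j
                slots[perch_i] = (ind, t, departure)
                busy_until[ind] = departure
                visit_rows.append((ind, day, feeder, perch_i, t, departure))
                end = min(departure, dep_j)
                if end > t:
                    if t_j < t or (t_j == t and j < ind):
                        source, target, latency = j, ind, t - t_j
                    else:
                        source, target, latency = ind, j, 0
                    same = class_of[ind] == class_of[j]
                    event_rows.append(
                        (day, feeder, source, target, t, latency, end - t, same)
                    )
                    key = (ind, j) if ind < j else (j, ind)
                    q[key] = q.get(key, 0.0) + (1.0 if same else -1.0)
            # both perches taken: moves on

    visits = pd.DataFrame(
        visit_rows, columns=["tag_id", "day", "feeder", "perch", "start", "end"]
    )
    events = pd.DataFrame(
        event_rows,
        columns=[
            "day",
            "feeder",
            "source",
            "target",
            "start",
            "latency",
            "duration",
            "is_same_class",
        ],
    )
    events = events.sort_values(
        ["day", "start", "feeder", "source", "target"], kind="mergesort"
    ).reset_index(drop=True)
    events.insert(0, "index", np.arange(1, len(events) + 1))
    events["outcome"] = np.where(events["is_same_class"], "success", "fail")
    events["is_affiliate"] = [
        frozenset((s, t)) in affiliates
        for s, t in zip(events["source"], events["target"])
    ]
    events = events[
        [
            "index",
            "day",
            "feeder",
            "source",
            "target",
            "start",
            "latency",
            "duration",
            "outcome",
            "is_same_class",
            "is_affiliate",
        ]
    ]
    return SimResult(individuals, affiliations, visits, events, config)


def visits_per_second(visits: pd.DataFrame) -> pd.DataFrame:
    """Expand visit intervals to one row per occupied second.

    Mirrors the RFID logger output: the tag code is recorded for each second
    during which the visitor occupied the perch.
    """
    if visits.empty:
        return pd.DataFrame(columns=["tag_id", "day", "feeder", "perch", "time"])
    lengths = (visits["end"] - visits["start"]).to_numpy(dtype=int)
    times = np.concatenate(
        [np.arange(s, e) for s, e in zip(visits["start"], visits["end"])]
    )
    out = pd.DataFrame(
        {
            "tag_id": np.repeat(visits["tag_id"].to_numpy(), lengths),
            "day": np.repeat(visits["day"].to_numpy(), lengths),
            "feeder": np.repeat(visits["feeder"].to_numpy(), lengths),
            "perch": np.repeat(visits["perch"].to_numpy(), lengths),
            "time": times,
        }
    )
    return out.sort_values(
        ["day", "feeder", "perch", "time"], kind="mergesort"
    ).reset_index(drop=True)


def replay_task_states(
    events: pd.DataFrame, config: SimConfig
) -> list[TaskState]:
    """Reconstruct the feeder state at the onset of each event.

    Runs the state machine per (day, feeder) along the event stream, advancing
    it through the gaps between events.  Useful for auditing how often events
    occurred against a locked-out feeder.
    """
    states: dict[tuple[int, int], tuple[TaskState, float]] = {}
    out: list[TaskState] = []
    for row in events.itertuples():
        key = (row.day, row.feeder)
        task, clock = states.get(key, (TaskState(), 0.0))
        gap = max(row.start - clock, 1e-9)
        task = step_task_state(
            task,
            "empty",
            False,
            gap,
            lockout_duration=config.lockout_duration,
            min_success_access=config.min_success_access,
        )
        out.append(task)
        task = step_task_state(
            task,
            "dyad",
            bool(row.is_same_class),
            max(row.duration, 1e-9),
            lockout_duration=config.lockout_duration,
            min_success_access=config.min_success_access,
        )
        states[key] = (task, row.start + row.duration)
    return out
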