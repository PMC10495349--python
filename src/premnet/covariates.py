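"""Time-varying network statistics used as relational-event-model covariates.

A relational event model explains the rate of dyadic events using covariates
computed from the interaction history *strictly before* each event.  This
module maintains that history incrementally (:class:`NetworkState`) and
assembles paired case-control design matrices for the eight model
specifications used in the analysis:

========  =======================================================================
model id  covariates (all computed from prior observed events only)
========  =======================================================================
M1        participants' cumulative counts of prior same-class and
          different-class events (individual performance; successful events)
M2        participants' numbers of distinct repeated partners (>= 2 prior joint
          events), split by class match (individual performance)
M3        same-class indicator and its interaction with the event clock
          (per 1000 events) — dyadic assortment over time
M4        prior dyad experience bins (1-5, 6+) and their interactions with the
          same-class indicator, non-affiliate dyads only
M5        as M4, affiliate dyads only
M6        arrival latency x same-class indicator (coordination of arrivals)
M7        event duration x same-class indicator (coordination of durations)
M8        common-associate counts (any class, and same-class-only) and their
          interactions with the event clock — triadic closure
========  =======================================================================

Non-events (permuted counterparts) never update the history; they inherit the
event clock and day stratum of their paired observed event.  The exact
covariate lists are a reconstruction from the reported effect estimates; the
registry documents each term by name.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NetworkState",
    "bin_experience",
    "repeated_partner_count",
    "common_associates",
    "MODEL_IDS",
    "MODEL_REGISTRY",
    "ModelDefinition",
    "build_design",
]

EXPERIENCE_BINS = ("none", "low", "high")


def bin_experience(prior_count: int) -> str:
    """Bin a dyad's prior joint-event count: 0 -> none, 1-5 -> low, >=6 -> high."""
    if prior_count < 0:
        raise ValueError("prior_count must be non-negative")
    if prior_count == 0:
        return "none"
    return "low" if prior_count <= 5 else "high"


class NetworkState:
    """Incremental event-history state.

    Tracks, per individual, the multiset of past partners and per-class event
    counts, plus symmetric dyad counts and the number of events applied.  The
    treatment-class map is fixed at construction so class-conditional
    statistics can be computed without further arguments.
    """

    def __init__(self, class_of: Mapping[str, str]):
        self.class_of = dict(class_of)
        self.dyad_count: Counter = Counter()
        self.partner_counts: defaultdict[str, Counter] = defaultdict(Counter)
        self.class_event_count: defaultdict[str, Counter] = defaultdict(Counter)
        self.n_events = 0

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def apply(self, source: str, target: str) -> None:
        """Record one observed event (order of roles is irrelevant here)."""
        if source == target:
            raise ValueError("loop event: source equals target")
        self.dyad_count[self._key(source, target)] += 1
        self.partner_counts[source][target] += 1
        self.partner_counts[target][source] += 1
        match = "same" if self.class_of[source] == self.class_of[target] else "diff"
        self.class_event_count[source][match] += 1
        self.class_event_count[target][match] += 1
        self.n_events += 1

    def dyad_prior(self, a: str, b: str) -> int:
        return self.dyad_count[self._key(a, b)]

    def class_prior(self, individual: str, match: str) -> int:
        if match not in ("same", "diff"):
            raise ValueError("match must be 'same' or 'diff'")
        return self.class_event_count[individual][match]


def repeated_partner_count(
    state: NetworkState, individual: str, class_filter: str
) -> int:
    """Distinct partners with >= 2 prior joint events, filtered by class match.

    ``class_filter`` is ``"same"`` or ``"diff"`` relative to the focal
    individual's treatment class.
    """
    if class_filter not in ("same", "diff"):
        raise ValueError("class_filter must be 'same' or 'diff'")
    own = state.class_of[individual]
    count = 0
    for partner, n in state.partner_counts[individual].items():
        if n < 2:
            continue
        is_same = state.class_of[partner] == own
        if (class_filter == "same") == is_same:
            count += 1
    return count


def common_associates(
    state: NetworkState,
    dyad: tuple[str, str],
    same_class_only: bool = False,
    *,
    min_events: int = 1,
) -> int:
    """Third parties with prior events with *both* dyad members.

    With ``same_class_only`` the count is restricted to associates sharing
    the treatment class of both members, which is only defined when the dyad
    itself is same-class.  ``min_events`` is the per-member joint-event
    threshold for counting an associate (default 1).
    """
    a, b = dyad
    if a == b:
        raise ValueError("dyad members must be distinct")
    if same_class_only and state.class_of[a] != state.class_of[b]:
        raise ValueError(
            "same-class-only common associates undefined for a different-class dyad"
        )
    pa, pb = state.partner_counts[a], state.partner_counts[b]
    if len(pa) > len(pb):
        pa, pb = pb, pa
    count = 0
    for third, n in pa.items():
        if third in (a, b) or n < min_events or pb.get(third, 0) < min_events:
            continue
        if same_class_only and state.class_of[third] != state.class_of[a]:
            continue
        count += 1
    return count


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

PerEventBuilder = Callable[
    [NetworkState, "EventView"], tuple[float, ...]
]


@dataclass(frozen=True)
class EventView:
    """Minimal view of one (possibly permuted) event row."""

    source: str
    target: str
    clock: int  # 1-based global index of the paired observed event
    latency: float
    duration: float


@dataclass(frozen=True)
class ModelDefinition:
    """One entry of the model registry.

    ``subset`` restricts which *observed* events (with their paired
    non-events) enter the design; all observed events still update the
    history.  ``needs_history`` distinguishes models whose covariates depend
    on the incremental network state from those computable directly from the
    event row (the latter are built vectorized).
    """

    id: str
    level: str
    terms: tuple[str, ...]
    variant: str
    ci_level: float
    subset: str | None = None
    needs_history: bool = True
    per_event: PerEventBuilder | None = None

    def describe(self) -> dict:
        return {
            "model": self.id,
            "level": self.level,
            "terms": list(self.terms),
            "permutation_variant": self.variant,
            "ci_level": self.ci_level,
            "subset": self.subset,
            "clock_scaling": "per 1000 events",
        }


def _m1(state: NetworkState, ev: EventView) -> tuple[float, ...]:
    same = state.class_prior(ev.source, "same") + state.class_prior(ev.target, "same")
    diff = state.class_prior(ev.source, "diff") + state.class_prior(ev.target, "diff")
    return (float(same), float(diff))


def _m2(state: NetworkState, ev: EventView) -> tuple[float, ...]:
    same = repeated_partner_count(state, ev.source, "same") + repeated_partner_count(
        state, ev.target, "same"
    )
    diff = repeated_partner_count(state, ev.source, "diff") + repeated_partner_count(
        state, ev.target, "diff"
    )
    return (float(same), float(diff))


def _experience_terms(state: NetworkState, ev: EventView) -> tuple[float, ...]:
    prior = state.dyad_prior(ev.source, ev.target)
    b = bin_experience(prior)
    low = 1.0 if b == "low" else 0.0
    high = 1.0 if b == "high" else 0.0
    same = 1.0 if state.class_of[ev.source] == state.class_of[ev.target] else 0.0
    return (low, high, low * same, high * same)


def _m8(state: NetworkState, ev: EventView) -> tuple[float, ...]:
    any_n = float(common_associates(state, (ev.source, ev.target)))
    if state.class_of[ev.source] == state.class_of[ev.target]:
        same_n = float(
            common_associates(state, (ev.source, ev.target), same_class_only=True)
        )
    else:
        same_n = 0.0
    clock = ev.clock / 1000.0
    return (any_n, same_n, any_n * clock, same_n * clock)


MODEL_REGISTRY: dict[str, ModelDefinition] = {
    "M1": ModelDefinition(
        "M1",
        "individual",
        ("prior_same_class_events", "prior_diff_class_events"),
        "independent_labels",
        0.975,
        subset="success_only",
        per_event=_m1,
    ),
    "M2": ModelDefinition(
        "M2",
        "individual",
        ("repeat_partners_same", "repeat_partners_diff"),
        "independent_labels",
        0.975,
        subset="success_only",
        per_event=_m2,
    ),
    "M3": ModelDefinition(
        "M3",
        "dyad",
        ("same_class", "same_class_x_clock"),
        "joint_labels",
        0.95,
        needs_history=False,
    ),
    "M4": ModelDefinition(
        "M4",
        "dyad",
        ("exp_low", "exp_high", "exp_low_x_same", "exp_high_x_same"),
        "joint_labels",
        0.95,
        subset="non_affiliate",
        per_event=_experience_terms,
    ),
    "M5": ModelDefinition(
        "M5",
        "dyad",
        ("exp_low", "exp_high", "exp_low_x_same", "exp_high_x_same"),
        "joint_labels",
        0.95,
        subset="affiliate",
        per_event=_experience_terms,
    ),
    "M6": ModelDefinition(
        "M6",
        "coordination",
        ("latency_x_same",),
        "edge_weights",
        0.95,
        needs_history=False,
    ),
    "M7": ModelDefinition(
        "M7",
        "coordination",
        ("duration_x_same",),
        "edge_weights",
        0.95,
        needs_history=False,
    ),
    "M8": ModelDefinition(
        "M8",
        "network",
        (
            "common_any",
            "common_same_class",
            "common_any_x_clock",
            "common_same_class_x_clock",
        ),
        "joint_labels",
        0.95,
        per_event=_m8,
    ),
}

MODEL_IDS = tuple(MODEL_REGISTRY)


def _subset_mask(model: ModelDefinition, obs: pd.DataFrame) -> np.ndarray:
    if model.subset is None:
        return np.ones(len(obs), dtype=bool)
    if model.subset == "success_only":
        return obs["is_same_class"].to_numpy(dtype=bool)
    if model.subset == "affiliate":
        return obs["is_affiliate"].to_numpy(dtype=bool)
    if model.subset == "non_affiliate":
        return ~obs["is_affiliate"].to_numpy(dtype=bool)
    raise ValueError(f"unknown subset rule {model.subset!r}")


def _vector_terms(
    model: ModelDefinition,
    df: pd.DataFrame,
    clock: np.ndarray,
    class_of: Mapping[str, str],
) -> np.ndarray:
    cls = np.array([class_of[x] for x in df["source"]])
    clt = np.array([class_of[x] for x in df["target"]])
    same = (cls == clt).astype(float)
    if model.id == "M3":
        return np.column_stack([same, same * clock / 1000.0])
    if model.id == "M6":
        return np.column_stack([df["latency"].to_numpy(float) * same])
    if model.id == "M7":
        return np.column_stack([df["duration"].to_numpy(float) * same])
    raise ValueError(f"model {model.id} is not vectorizable")


def build_design(
    events: pd.DataFrame,
    nonevents: pd.DataFrame,
    model_id: str,
    class_of: Mapping[str, str],
) -> pd.DataFrame:
    """Assemble the paired case-control design matrix for one model.

    ``events`` is the observed, globally ordered event list; ``nonevents`` is
    the row-aligned permuted replicate.  The returned frame has two rows per
    retained event (observed first, then its non-event), sharing
    ``event_index``, ``stratum`` (day) and clock, plus one column per model
    term.  History-based covariates for row *k* reflect only observed events
    ``1..k-1``; non-events never enter the state.
    """
    if model_id not in MODEL_REGISTRY:
        raise ValueError(f"unknown model id {model_id!r}")
    if len(events) != len(nonevents):
        raise ValueError("events and nonevents must be row-aligned")
    model = MODEL_REGISTRY[model_id]
    n = len(events)
    clock = events["index"].to_numpy(dtype=int)
    keep = _subset_mask(model, events)

    if not model.needs_history:
        x_obs = _vector_terms(model, events, clock, class_of)
        x_non = _vector_terms(model, nonevents, clock, class_of)
    else:
        state = NetworkState(class_of)
        x_obs = np.empty((n, len(model.terms)))
        x_non = np.empty((n, len(model.terms)))
        src_o = events["source"].to_numpy()
        tgt_o = events["target"].to_numpy()
        lat_o = events["latency"].to_numpy(float)
        dur_o = events["duration"].to_numpy(float)
        src_p = nonevents["source"].to_numpy()
        tgt_p = nonevents["target"].to_numpy()
        lat_p = nonevents["latency"].to_numpy(float)
        dur_p = nonevents["duration"].to_numpy(float)
        fn = model.per_event
        for k in range(n):
            if keep[k]:
                x_obs[k] = fn(
                    state,
                    EventView(src_o[k], tgt_o[k], int(clock[k]), lat_o[k], dur_o[k]),
                )
                x_non[k] = fn(
                    state,
                    EventView(src_p[k], tgt_p[k], int(clock[k]), lat_p[k], dur_p[k]),
                )
            state.apply(src_o[k], tgt_o[k])

    idx = np.flatnonzero(keep)
    rows = np.empty(2 * len(idx), dtype=int)
    rows[0::2] = idx
    rows[1::2] = idx
    x = np.empty((2 * len(idx), len(model.terms)))
    x[0::2] = x_obs[idx]
    x[1::2] = x_non[idx]
    out = pd.DataFrame(x, columns=list(model.terms))
    out.insert(0, "event_index", clock[rows])
    out.insert(1, "is_observed", np.tile([True, False], len(idx)))
    out.insert(2, "stratum", events["day"].to_numpy()[rows])
    return out
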