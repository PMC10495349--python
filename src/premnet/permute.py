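"""Constrained data-stream permutations generating "non-events".

The permutation null preserves the structure of data collection — event
counts, timestamps and the day x feeder subsetting of the stream — and
randomizes only participant labels (or edge weights).  Because labels never
cross day x feeder subsets, individuals can never appear on a day before
their first observed visit, which is how mid-experiment entrants (fledged
juveniles) are handled without any special casing.

Four variants are provided:

``independent_labels``
    Source and target columns shuffled separately within each subset;
    preserves every individual's per-role event counts.
``joint_labels``
    All ``2n`` labels of a subset pooled and redistributed over the ``2n``
    role slots; preserves each individual's total participation count but not
    its role split.
``edge_weights``
    Only latency/duration values are shuffled among the subset's events;
    labels and roles untouched.
``target_only``
    Only the target column shuffled.  Experimental: a placeholder for a
    fourth, role-asymmetric randomization, not asserted to match any
    published variant.

Label shuffles can produce "loops" (an individual drawn as both source and
target of one record).  A subset is re-randomized until loop-free, up to
``max_reshuffles`` attempts (default 10,000); if loops persist, constrained
pairwise label swaps repair them: each looped record swaps its source or
target (chosen at random) with a random record not featuring the looped
individual in either role.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "VARIANTS",
    "PermutationPlan",
    "permute_subset",
    "resolve_loops",
    "generate_replicates",
]

VARIANTS = ("independent_labels", "joint_labels", "edge_weights", "target_only")
WEIGHT_COLUMNS = ("latency", "duration")


@dataclass(frozen=True)
class PermutationPlan:
    """How to randomize an event stream."""

    variant: str
    seed: int
    max_reshuffles: int = 10000
    subset_keys: tuple[str, str] = ("day", "feeder")

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.max_reshuffles < 1:
            raise ValueError("max_reshuffles must be >= 1")


def _shuffle_labels(
    sources: np.ndarray,
    targets: np.ndarray,
    variant: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(sources)
    if variant == "independent_labels":
        return rng.permutation(sources), rng.permutation(targets)
    if variant == "joint_labels":
        pool = rng.permutation(np.concatenate([sources, targets]))
        return pool[:n], pool[n:]
    if variant == "target_only":
        return sources.copy(), rng.permutation(targets)
    raise ValueError(f"variant {variant!r} does not shuffle labels")


def resolve_loops(
    sources: np.ndarray,
    targets: np.ndarray,
    rng: np.random.Generator,
    *,
    reshuffle: Callable[[np.random.Generator], tuple[np.ndarray, np.ndarray]]
    | None = None,
    max_reshuffles: int = 10000,
    max_swap_draws: int = 10000,
) -> tuple[np.ndarray, np.ndarray]:
    """Return a loop-free label assignment.

    First re-randomizes via ``reshuffle`` (if given) until no loops remain or
    ``max_reshuffles`` attempts are spent; then repairs remaining loops with
    constrained pairwise swaps.  For each loop, a random other record not
    featuring the looped individual in either role is drawn and either the
    source or the target label (chosen at random) is exchanged, creating two
    valid records; draws that would re-create a loop are rejected and
    redrawn, up to ``max_swap_draws`` times.
    """
    attempts = 0
    while (sources == targets).any():
        if reshuffle is None or attempts >= max_reshuffles:
            break
        sources, targets = reshuffle(rng)
        attempts += 1

    if not (sources == targets).any():
        return sources, targets

    sources = sources.copy()
    targets = targets.copy()
    n = len(sources)
    loop_idx = list(np.flatnonzero(sources == targets))
    for i in loop_idx:
        if sources[i] != targets[i]:
            continue  # repaired as a side effect of an earlier swap
        looped = sources[i]
        eligible = np.flatnonzero((sources != looped) & (targets != looped))
        eligible = eligible[eligible != i]
        if len(eligible) == 0:
            raise RuntimeError(
                f"no eligible swap partner for looped individual {looped!r} "
                f"in a subset of {n} events"
            )
        for _ in range(max_swap_draws):
            j = int(rng.choice(eligible))
            col = "source" if rng.integers(2) else "target"
            s, t = (sources, targets) if col == "source" else (targets, sources)
            s[i], s[j] = s[j], s[i]
            if sources[i] != targets[i] and sources[j] != targets[j]:
                break
            s[i], s[j] = s[j], s[i]  # undo and redraw
        else:
            raise RuntimeError(
                f"could not repair loop for {looped!r} within {max_swap_draws} draws"
            )
    assert not (sources == targets).any()
    return sources, targets


def permute_subset(
    subset: pd.DataFrame,
    variant: str,
    rng: np.random.Generator,
    *,
    max_reshuffles: int = 10000,
) -> pd.DataFrame:
    """Permute one day x feeder subset; returns a copy with permuted columns."""
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    out = subset.copy()
    if variant == "edge_weights":
        order = rng.permutation(len(subset))
        for col in WEIGHT_COLUMNS:
            if col in out.columns:
                out[col] = subset[col].to_numpy()[order]
        return out

    src = subset["source"].to_numpy()
    tgt = subset["target"].to_numpy()

    def reshuffle(r: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        return _shuffle_labels(src, tgt, variant, r)

    new_src, new_tgt = reshuffle(rng)
    new_src, new_tgt = resolve_loops(
        new_src, new_tgt, rng, reshuffle=reshuffle, max_reshuffles=max_reshuffles
    )
    out["source"] = new_src
    out["target"] = new_tgt
    return out


def _subset_positions(
    events: pd.DataFrame, keys: list[str]
) -> list[np.ndarray]:
    """Row positions of each day x feeder subset, in sorted key order."""
    grouped = events.groupby(keys, sort=True).indices
    return [np.asarray(grouped[k]) for k in sorted(grouped)]


def _permute_arrays(
    events: pd.DataFrame,
    positions: list[np.ndarray],
    variant: str,
    rng: np.random.Generator,
    max_reshuffles: int,
) -> pd.DataFrame:
    out = events.copy()
    if variant == "edge_weights":
        weights = {
            col: events[col].to_numpy(copy=True)
            for col in WEIGHT_COLUMNS
            if col in events.columns
        }
        for pos in positions:
            order = rng.permutation(len(pos))
            for col, arr in weights.items():
                arr[pos] = arr[pos][order]
        for col, arr in weights.items():
            out[col] = arr
        return out

    src = events["source"].to_numpy(copy=True)
    tgt = events["target"].to_numpy(copy=True)
    for pos in positions:
        s0, t0 = src[pos], tgt[pos]

        def reshuffle(r: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
            return _shuffle_labels(s0, t0, variant, r)

        s, t = reshuffle(rng)
        s, t = resolve_loops(
            s, t, rng, reshuffle=reshuffle, max_reshuffles=max_reshuffles
        )
        src[pos] = s
        tgt[pos] = t
    out["source"] = src
    out["target"] = tgt
    return out


def permute_events(
    events: pd.DataFrame,
    plan: PermutationPlan,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Permute a full event stream, one subset at a time, in stable order."""
    positions = _subset_positions(events, list(plan.subset_keys))
    return _permute_arrays(events, positions, plan.variant, rng, plan.max_reshuffles)


def generate_replicates(
    events: pd.DataFrame,
    plan: PermutationPlan,
    n_replicates: int,
    class_of: dict[str, str] | None = None,
) -> Iterator[pd.DataFrame]:
    """Yield ``n_replicates`` independently permuted copies of the stream.

    Replicate *r* uses the seeded substream ``(plan.seed, r)`` and is fully
    reproducible from the plan alone.  If ``class_of`` is given, the
    class-match and outcome columns of each replicate are recomputed from the
    permuted labels (they are meaningless otherwise and dropped).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    positions = _subset_positions(events, list(plan.subset_keys))
    for r in range(n_replicates):
        rng = np.random.default_rng([plan.seed, r])
        rep = _permute_arrays(
            events, positions, plan.variant, rng, plan.max_reshuffles
        )
        if plan.variant != "edge_weights":
            if class_of is not None:
                same = np.array(
                    [
                        class_of[s] == class_of[t]
                        for s, t in zip(rep["source"], rep["target"])
                    ],
                    dtype=bool,
                )
                rep["is_same_class"] = same
                rep["outcome"] = np.where(same, "success", "fail")
            else:
                rep = rep.drop(
                    columns=[
                        c
                        for c in ("is_same_class", "outcome", "is_affiliate")
                        if c in rep.columns
                    ]
                )
        yield rep
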