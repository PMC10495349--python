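"""Non-model permutation tests on the event stream.

Two descriptive tests complement the pREMs: whether the observed percentage
of successful (same-class) events exceeds the range expected under random
treatment-class combination, and how the cumulative daily success/fail
differential departs from its permutation envelope over the course of the
experiment.  Both compare the observed statistic to the 2.5% and 97.5%
quantiles of the statistic across permuted replicates.  A one-sided exact
binomial test quantifies over-representation of a dyad subset (e.g.
affiliated dyads) among events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NullEnvelope",
    "BinomialShareResult",
    "success_proportion_test",
    "cumulative_differential",
    "binomial_share_test",
    "plot_differential",
]


@dataclass
class NullEnvelope:
    """Observed statistic against its permutation null distribution.

    ``observed``/``median``/``lower``/``upper`` are scalars for the success
    proportion and per-day arrays for the cumulative differential;
    ``exceeds`` marks where the observed value falls outside [lower, upper].
    """

    observed: float | np.ndarray
    replicates: np.ndarray
    median: float | np.ndarray
    lower: float | np.ndarray
    upper: float | np.ndarray
    exceeds: bool | np.ndarray
    days: np.ndarray | None = None


def _same_class_mask(df: pd.DataFrame, class_of: Mapping[str, str]) -> np.ndarray:
    if "is_same_class" in df.columns and df["is_same_class"].notna().all():
        return df["is_same_class"].to_numpy(bool)
    return np.array(
        [class_of[s] == class_of[t] for s, t in zip(df["source"], df["target"])],
        dtype=bool,
    )


def success_proportion_test(
    events: pd.DataFrame,
    replicates: Iterable[pd.DataFrame],
    class_of: Mapping[str, str],
) -> NullEnvelope:
    """Observed % successful events vs the permuted 95% interval.

    Replicates should come from the joint-label variant, so that the null
    holds participation fixed but randomizes class combinations.  Percentages
    are on the 0-100 scale.
    """
    if len(events) == 0:
        raise ValueError("no events")
    observed = 100.0 * _same_class_mask(events, class_of).mean()
    rep_props = np.array(
        [100.0 * _same_class_mask(rep, class_of).mean() for rep in replicates]
    )
    if len(rep_props) == 0:
        raise ValueError("no replicates supplied")
    lower = float(np.quantile(rep_props, 0.025))
    upper = float(np.quantile(rep_props, 0.975))
    return NullEnvelope(
        observed=float(observed),
        replicates=rep_props,
        median=float(np.median(rep_props)),
        lower=lower,
        upper=upper,
        exceeds=bool(observed > upper),
    )


def _daily_cumulative(df: pd.DataFrame, days: np.ndarray, same: np.ndarray) -> np.ndarray:
    day_vals = df["day"].to_numpy()
    diff = np.zeros(len(days))
    pos = {d: i for i, d in enumerate(days)}
    idx = np.array([pos[d] for d in day_vals])
    np.add.at(diff, idx, np.where(same, 1.0, -1.0))
    return np.cumsum(diff)


def cumulative_differential(
    events: pd.DataFrame,
    replicates: Iterable[pd.DataFrame],
    class_of: Mapping[str, str],
) -> NullEnvelope:
    """Cumulative daily (successes - failures) with its permutation envelope.

    The observed series uses observed outcomes; replicate series recompute
    outcomes from the permuted labels via class match.  Quantiles are
    pointwise per day.
    """
    if len(events) == 0:
        raise ValueError("no events")
    days = np.sort(events["day"].unique())
    observed = _daily_cumulative(events, days, _same_class_mask(events, class_of))
    series = np.array(
        [
            _daily_cumulative(rep, days, _same_class_mask(rep, class_of))
            for rep in replicates
        ]
    )
    if series.size == 0:
        raise ValueError("no replicates supplied")
    lower = np.quantile(series, 0.025, axis=0)
    upper = np.quantile(series, 0.975, axis=0)
    return NullEnvelope(
        observed=observed,
        replicates=series,
        median=np.median(series, axis=0),
        lower=lower,
        upper=upper,
        exceeds=(observed > upper) | (observed < lower),
        days=days,
    )


@dataclass(frozen=True)
class BinomialShareResult:
    event_share: float
    dyad_share: float
    p_value: float
    k_events: int
    n_events: int
    k_dyads: int
    n_dyads: int


def binomial_share_test(
    k_events: int,
    n_events: int,
    k_dyads: int,
    n_dyads: int,
    *,
    alternative: str = "greater",
) -> BinomialShareResult:
    """Is a dyad subset over-represented among events?

    Compares the share of events produced by ``k_dyads`` of ``n_dyads`` dyads
    (``k_events`` of ``n_events`` events) to the share expected if every dyad
    contributed equally, via an exact binomial test with success rate
    ``k_dyads / n_dyads``.  One-sided ("greater") by default, matching the
    over-representation question; pass ``alternative="two-sided"`` otherwise.
    """
    if n_events <= 0 or n_dyads <= 0:
        raise ValueError("n_events and n_dyads must be positive")
    if not (0 <= k_events <= n_events) or not (0 <= k_dyads <= n_dyads):
        raise ValueError("counts out of range")
    rate = k_dyads / n_dyads
    p = stats.binomtest(k_events, n_events, rate, alternative=alternative).pvalue
    return BinomialShareResult(
        event_share=k_events / n_events,
        dyad_share=rate,
        p_value=float(p),
        k_events=k_events,
        n_events=n_events,
        k_dyads=k_dyads,
        n_dyads=n_dyads,
    )


def plot_differential(envelope: NullEnvelope, path) -> None:
    """Line-plus-envelope plot of the cumulative success/fail differential."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if envelope.days is None:
        raise ValueError("envelope has no daily series")
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.fill_between(
        envelope.days, envelope.lower, envelope.upper, color="tab:red", alpha=0.25,
        label="permuted 95% interval",
    )
    ax.plot(envelope.days, envelope.median, color="tab:red", label="permuted median")
    ax.plot(envelope.days, envelope.observed, color="black", label="observed")
    ax.set_xlabel("day")
    ax.set_ylabel("cumulative success - fail")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
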