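"""Permuted relational event models (pREMs).

Each observed event is paired with the single "non-event" generated for it by
the data-stream permutation.  With exactly one case and one control per risk
set, the stratified Cox partial likelihood reduces *exactly* to the matched
conditional-logistic log-likelihood

    sum_k [ x_k' beta - log(exp(x_k' beta) + exp(z_k' beta)) ]

where ``x_k`` and ``z_k`` are the covariate vectors of event ``k`` and its
non-event.  Writing ``d_k = x_k - z_k`` this is a logistic likelihood in the
within-pair differences, maximized here by Newton iteration with the analytic
gradient and Hessian.  Fitting one model per permuted replicate yields a
distribution of coefficients per term; the median is the effect estimate, its
quantile interval the confidence interval, and exponentiation gives incidence
rate ratios (IRRs) relative to the permutation baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import covariates as cov
from . import permute as perm

__all__ = [
    "FitResult",
    "TermSummary",
    "PremResult",
    "splice",
    "fit_partial_likelihood",
    "run_prem",
    "predict_rates",
]

MAX_ITER = 50
SCORE_TOL = 1e-8
SEPARATION_BOUND = 30.0


@dataclass
class FitResult:
    """One replicate's fit."""

    terms: tuple[str, ...]
    coef: np.ndarray  # NaN for non-estimable terms
    converged: bool
    n_pairs: int
    flagged: tuple[str, ...] = ()  # terms with zero within-pair variance
    message: str = ""


def splice(observed: pd.DataFrame, replicate: pd.DataFrame) -> pd.DataFrame:
    """Interleave observed events with their permuted non-events.

    Returns ``2n`` rows: row ``2k`` is observed event ``k+1`` (case), row
    ``2k+1`` its non-event (control); both share index, day, feeder, start
    time and therefore clock and stratum.
    """
    if len(observed) != len(replicate):
        raise ValueError("observed and replicate lengths differ")
    shared = ["index", "day", "feeder", "start"]
    for col in shared:
        if col in replicate.columns and not np.array_equal(
            observed[col].to_numpy(), replicate[col].to_numpy()
        ):
            raise ValueError(f"replicate not row-aligned with observed on {col!r}")
    obs = observed.copy()
    non = replicate.copy()
    obs["is_observed"] = True
    non["is_observed"] = False
    order = np.empty(2 * len(obs), dtype=int)
    order[0::2] = np.arange(len(obs))
    order[1::2] = np.arange(len(obs)) + len(obs)
    out = pd.concat([obs, non], ignore_index=True).iloc[order].reset_index(drop=True)
    return out


def _loglik(d: np.ndarray, beta: np.ndarray) -> float:
    eta = d @ beta
    return float(np.sum(eta - np.logaddexp(0.0, eta)))


def fit_partial_likelihood(design: pd.DataFrame) -> FitResult:
    """Maximize the paired partial likelihood on a spliced design matrix.

    ``design`` comes from :func:`premnet.covariates.build_design`: alternating
    observed/non-event rows with one column per term.  Terms with zero
    within-pair variance carry no information and are returned as NaN with a
    flag; complete separation is reported as non-convergence with the
    offending term named.
    """
    meta = {"event_index", "is_observed", "stratum"}
    terms = tuple(c for c in design.columns if c not in meta)
    x = design[list(terms)].to_numpy(float)
    obs = design["is_observed"].to_numpy(bool)
    if len(design) % 2 or not obs[0::2].all() or obs[1::2].any():
        raise ValueError("design must alternate observed / non-event rows")
    d = x[0::2] - x[1::2]
    n_pairs = d.shape[0]
    if n_pairs == 0:
        raise ValueError("empty design")

    active = np.flatnonzero(np.max(np.abs(d), axis=0) > 0)
    flagged = tuple(terms[j] for j in range(len(terms)) if j not in active)
    coef = np.full(len(terms), np.nan)
    if len(active) == 0:
        return FitResult(terms, coef, True, n_pairs, flagged, "no informative terms")

    # exact separation: a term whose within-pair differences never change sign
    # drives the likelihood monotonically, so the maximizer is infinite
    for j in active:
        col = d[:, j]
        if (col >= 0).all() or (col <= 0).all():
            return FitResult(
                terms,
                coef,
                False,
                n_pairs,
                flagged,
                f"separation: term {terms[j]!r} perfectly splits cases and controls",
            )

    da = d[:, active]
    beta = np.zeros(len(active))
    ll = _loglik(da, beta)
    converged = False
    message = ""
    for _ in range(MAX_ITER):
        eta = da @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        score = da.T @ (1.0 - p)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        w = p * (1.0 - p)
        hess = (da * w[:, None]).T @ da
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, score, rcond=None)[0]
        # step-halving to guarantee ascent
        for _ in range(30):
            new = beta + step
            new_ll = _loglik(da, new)
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
        beta, ll = new, new_ll
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            worst = terms[active[int(np.argmax(np.abs(beta)))]]
            message = f"separation suspected on term {worst!r}"
            break
    else:
        message = "Newton iteration did not converge"

    coef[active] = beta
    return FitResult(terms, coef, converged, n_pairs, flagged, message)


@dataclass
class TermSummary:
    term: str
    median: float
    ci_low: float
    ci_high: float
    irr: float
    irr_low: float
    irr_high: float
    significant: bool
    n_samples: int


@dataclass
class PremResult:
    """Aggregated pREM output for one model."""

    model_id: str
    ci_level: float
    terms: dict[str, TermSummary]
    samples: pd.DataFrame = field(repr=False)  # one row per replicate
    n_replicates: int = 0
    n_dropped: int = 0
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "ci_level": self.ci_level,
            "n_replicates": self.n_replicates,
            "n_dropped": self.n_dropped,
            "warning": self.warning,
            "terms": {
                t: {
                    "median": s.median,
                    "ci": [s.ci_low, s.ci_high],
                    "irr": s.irr,
                    "irr_ci": [s.irr_low, s.irr_high],
                    "significant": s.significant,
                    "n_samples": s.n_samples,
                }
                for t, s in self.terms.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def summarize_samples(
    samples: pd.DataFrame, ci_level: float, *, n_dropped: int = 0, model_id: str = ""
) -> PremResult:
    """Turn a replicate x term coefficient table into a :class:`PremResult`.

    Quantile CIs use linear interpolation; a term is significant when its
    interval excludes zero on the coefficient scale.  Non-estimable
    replicates (NaN) are ignored per term.
    """
    alpha = (1.0 - ci_level) / 2.0
    terms: dict[str, TermSummary] = {}
    for term in samples.columns:
        vals = samples[term].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            terms[term] = TermSummary(
                term, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False, 0
            )
            continue
        med = float(np.median(vals))
        lo = float(np.quantile(vals, alpha))
        hi = float(np.quantile(vals, 1.0 - alpha))
        terms[term] = TermSummary(
            term,
            med,
            lo,
            hi,
            float(np.exp(med)),
            float(np.exp(lo)),
            float(np.exp(hi)),
            bool(lo > 0.0 or hi < 0.0),
            len(vals),
        )
    n_rep = len(samples)
    warning = None
    if n_rep and n_dropped > 0.1 * (n_rep + n_dropped):
        warning = (
            f"{n_dropped} of {n_rep + n_dropped} replicates did not converge"
        )
    return PremResult(
        model_id, ci_level, terms, samples, n_rep, n_dropped, warning
    )


def run_prem(
    events: pd.DataFrame,
    model_id: str,
    class_of: Mapping[str, str],
    *,
    n_replicates: int = 10000,
    seed: int = 0,
    max_reshuffles: int = 10000,
) -> PremResult:
    """Full pREM pipeline for one model: permute, splice, build, fit, pool.

    The permutation variant and CI level come from the model registry
    (independent label shuffles for the individual-level models M1-M2, joint
    label pooling for the dyad/network models M3-M5 and M8, edge-weight
    shuffles for the coordination models M6-M7; CI 97.5% for M1-M2 as a
    multiple-testing correction, 95% otherwise).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    model = cov.MODEL_REGISTRY[model_id]
    plan = perm.PermutationPlan(
        variant=model.variant, seed=seed, max_reshuffles=max_reshuffles
    )
    rows = []
    n_dropped = 0
    for rep in perm.generate_replicates(events, plan, n_replicates):
        design = cov.build_design(events, rep, model_id, class_of)
        fit = fit_partial_likelihood(design)
        if not fit.converged:
            n_dropped += 1
            continue
        rows.append(fit.coef)
    samples = pd.DataFrame(rows, columns=list(model.terms))
    return summarize_samples(
        samples, model.ci_level, n_dropped=n_dropped, model_id=model_id
    )


def predict_rates(
    result: PremResult,
    baseline_rate: float,
    profile: Mapping[str, float],
    *,
    interval: float = 0.95,
) -> dict:
    """Expected events per hour for a covariate profile.

    Multiplies the baseline rate by ``exp(profile . beta_r)`` for every
    replicate ``r`` and summarizes the resulting rate distribution by its
    median and central prediction interval.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    unknown = set(profile) - set(result.samples.columns)
    if unknown:
        raise ValueError(f"unknown term(s) in profile: {sorted(unknown)}")
    eta = np.zeros(len(result.samples))
    for term, value in profile.items():
        eta = eta + value * result.samples[term].to_numpy(float)
    rates = baseline_rate * np.exp(eta)
    rates = rates[np.isfinite(rates)]
    a = (1.0 - interval) / 2.0
    return {
        "median": float(np.median(rates)),
        "lower": float(np.quantile(rates, a)),
        "upper": float(np.quantile(rates, 1.0 - a)),
        "n_samples": int(len(rates)),
    }
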