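"""Survival machinery: Kaplan-Meier, log-rank, Cox PH, Harrell's C.

KM, the log-rank test and the concordance index are implemented directly in
numpy/scipy: the cutoff optimizer evaluates them on the order of 1e5 times
per search, and the concordance index follows a pinned pair convention
(below).  The Cox model is delegated to lifelines (Efron tie handling, Wald
intervals).

Concordance convention (Harrell): a pair (i, j) is comparable iff the
strictly shorter observed time belongs to a subject whose event was
observed.  Pairs with equal observed times are incomparable — including the
equal-event-time case.  Over comparable pairs, the pair is concordant when
the shorter-lived subject carries the strictly higher predicted risk; risk
ties contribute 1/2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class SurvivalSample:
    """Aligned observed times (months) and event indicators."""

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if np.any(self.times < 0):
            raise ValueError("negative survival times")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class SurvivalCurve:
    times: np.ndarray          # distinct event times, increasing
    survival: np.ndarray       # S(t) at each event time
    at_risk: np.ndarray        # n at risk just before each event time
    median: Optional[float]    # first time with S <= 0.5, None if unreached

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "n_at_risk": self.at_risk,
                             "survival": self.survival})


def km_estimate(sample: SurvivalSample) -> SurvivalCurve:
    """Product-limit estimator.  The median is the smallest observed event
    time at which the step function S(t) drops to 0.5 or below (S is
    right-continuous); None if S never reaches 0.5."""
    if len(sample) == 0:
        raise ValueError("empty sample")
    order = np.argsort(sample.times, kind="stable")
    t, e = sample.times[order], sample.events[order]
    event_times = np.unique(t[e])
    if event_times.size == 0:
        return SurvivalCurve(np.empty(0), np.empty(0), np.empty(0, dtype=int),
                             None)
    n = t.size
    # at risk just before each event time; deaths at each event time
    at_risk = n - np.searchsorted(t, event_times, side="left")
    deaths = np.array([np.sum(e & (t == et)) for et in event_times])
    surv = np.cumprod(1.0 - deaths / at_risk)
    below = np.nonzero(surv <= 0.5)[0]
    median = float(event_times[below[0]]) if below.size else None
    return SurvivalCurve(event_times, surv, at_risk.astype(int), median)


def km_median(times: np.ndarray, events: np.ndarray) -> float:
    """Fast KM median for internal use; +inf when S never reaches 0.5."""
    order = np.argsort(times, kind="stable")
    t, e = np.asarray(times, float)[order], np.asarray(events, bool)[order]
    if not e.any():
        return np.inf
    event_times = np.unique(t[e])
    at_risk = t.size - np.searchsorted(t, event_times, side="left")
    deaths = np.bincount(np.searchsorted(event_times, t[e]),
                         minlength=event_times.size)
    surv = np.cumprod(1.0 - deaths / at_risk)
    below = np.nonzero(surv <= 0.5)[0]
    return float(event_times[below[0]]) if below.size else np.inf


def logrank_test(groups: Sequence[SurvivalSample]) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi2, p) with k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    times = np.concatenate([g.times for g in groups])
    events = np.concatenate([g.events for g in groups])
    labels = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    chi2 = _logrank_chi2(times, events, labels, len(groups))
    p = float(stats.chi2.sf(chi2, df=len(groups) - 1))
    return chi2, p


def _logrank_chi2(times, events, labels, k: int) -> float:
    """Log-rank chi-square for integer group labels 0..k-1 (vectorized)."""
    event_times = np.unique(times[events])
    if event_times.size == 0:
        return 0.0
    D = event_times.size
    # at risk per group at each event time: n_g - #{t_g < et}
    at_risk = np.empty((D, k))
    deaths = np.empty((D, k))
    for g in range(k):
        tg = np.sort(times[labels == g])
        at_risk[:, g] = tg.size - np.searchsorted(tg, event_times, side="left")
        te = np.sort(times[(labels == g) & events])
        deaths[:, g] = (np.searchsorted(te, event_times, side="right")
                        - np.searchsorted(te, event_times, side="left"))
    N = at_risk.sum(axis=1)
    d = deaths.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = at_risk * (d / N)[:, None]
        # hypergeometric variance of deaths in each group at each time
        frac = at_risk / N[:, None]
        vmult = np.where(N > 1, d * (N - d) / (N - 1), 0.0)
        var = frac * (1 - frac) * vmult[:, None]
    O_E = np.nansum(deaths - expected, axis=0)[:-1]
    # covariance matrix of the first k-1 group statistics
    cov = np.zeros((k - 1, k - 1))
    for a in range(k - 1):
        for b in range(k - 1):
            if a == b:
                cov[a, b] = np.nansum(var[:, a])
            else:
                cov[a, b] = -np.nansum(
                    frac[:, a] * frac[:, b]
                    * np.where(N > 1, d * (N - d) / (N - 1), 0.0))
    if k == 2:
        v = cov[0, 0]
        return float(O_E[0] ** 2 / v) if v > 0 else 0.0
    try:
        sol = np.linalg.solve(cov, O_E)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(cov, O_E, rcond=None)[0]
    return float(O_E @ sol)


def logrank_chi2_two_group(times, events, in_high: np.ndarray) -> float:
    """Two-group log-rank chi-square from a boolean group mask (fast path
    used by the cutoff proposer)."""
    return _logrank_chi2(np.asarray(times, float), np.asarray(events, bool),
                         in_high.astype(int), 2)


def cox_fit(sample: SurvivalSample, covariates) -> pd.DataFrame:
    """Cox proportional-hazards fit (lifelines; Efron tie handling).

    Returns a DataFrame indexed by covariate with columns ``log_hr``, ``hr``,
    ``ci_lower``, ``ci_upper`` (95% Wald intervals on the hazard-ratio
    scale).  Raises on a sample without events; warns (and returns the
    possibly extreme estimate) under separation.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceWarning

    if not sample.events.any():
        raise ValueError("no events observed; Cox model is unidentified")
    X = pd.DataFrame(np.atleast_2d(np.asarray(covariates, dtype=float).T).T)
    X.columns = [f"x{i}" for i in range(X.shape[1])]
    df = X.copy()
    df["time"] = sample.times
    df["event"] = sample.events.astype(int)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        cph.fit(df, duration_col="time", event_col="event")
    out = pd.DataFrame({
        "log_hr": cph.params_,
        "hr": np.exp(cph.params_),
        "ci_lower": np.exp(cph.confidence_intervals_.iloc[:, 0]),
        "ci_upper": np.exp(cph.confidence_intervals_.iloc[:, 1]),
    })
    if np.any(np.abs(cph.params_) > 10):
        logger.warning("possible separation: |log HR| > 10")
    return out


def harrell_c(sample: SurvivalSample, risks) -> float:
    """Harrell's concordance index under the convention in the module
    docstring.  Returns NaN (logged) when no pair is comparable."""
    risks = np.asarray(risks, dtype=float)
    if risks.shape != sample.times.shape:
        raise ValueError("risks must align with the sample")
    t, e = sample.times, sample.events
    # pair (i, j) comparable iff t_i < t_j and event_i
    shorter = t[:, None] < t[None, :]
    comparable = shorter & e[:, None]
    higher = risks[:, None] > risks[None, :]
    tied = risks[:, None] == risks[None, :]
    n_comp = comparable.sum()
    if n_comp == 0:
        logger.warning("no comparable pairs; concordance undefined")
        return float("nan")
    concordant = (comparable & higher).sum() + 0.5 * (comparable & tied).sum()
    return float(concordant / n_comp)


def export_curve_tsv(curve: SurvivalCurve, path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
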