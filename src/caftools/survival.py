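"""Kaplan-Meier estimation, log-rank testing and min-p biomarker dichotomization.

The centrepiece is :func:`iterative_cutoff`: given a cohort with follow-up
time, event indicator and a continuous biomarker (e.g. log2 probe
intensity), it scans every admissible split of the cohort into "Low" and
"High" biomarker groups, computes the two-group log-rank test at each split,
and returns the cutoff that maximally discriminates the two survival curves
(minimal p).  When the median split is among the p-minimizing candidates it
is preferred — the conventional median dichotomization then wins over an
arbitrary optimum.

A min-p search performs many correlated tests without correction, so the
resulting p-value is anti-conservative: under the null the chance that the
minimal p falls below 0.05 is well above 5%.  This inflation is a
documented property of the procedure (see docs/methods.md); the search is
useful for locating a threshold, not for calibrated inference at it.

The log-rank statistic and the product-limit estimator are implemented
directly on risk-set tables (and cross-checked against lifelines in the
test suite); keeping them in-module makes the candidate scan cheap enough
to run hundreds of replicates in simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve: S(t) right-continuous, S(0) = 1."""

    event_times: np.ndarray  # distinct times with >= 1 event, ascending
    survival: np.ndarray  # S(t) just after each event time

    def at(self, t: float) -> float:
        """Survival probability at time t (step function, right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times, "survival": self.survival})


@dataclass(frozen=True)
class LogrankResult:
    statistic: float  # chi-square, 1 df
    p_value: float


@dataclass(frozen=True)
class CutoffResult:
    """Outcome of the iterative log-rank cutoff search."""

    cutoff: float
    n_low: int
    n_high: int
    p_values: pd.DataFrame  # one row per candidate: cutoff, n_low, n_high, p
    chosen_p: float
    used_median_fallback: bool


def _check_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    if t.shape != e.shape:
        raise ValueError("times and events must have the same length")
    if (t < 0).any():
        raise ValueError("negative follow-up time")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return t, e


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimate of the survival function."""
    t, e = _check_times_events(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    distinct = np.unique(t[e == 1])
    # at risk just before u: all subjects with time >= u
    n_at_risk = t.size - np.searchsorted(t, distinct, side="left")
    d = np.array([int(((t == u) & (e == 1)).sum()) for u in distinct])
    surv = np.cumprod(1.0 - d / n_at_risk)
    return KMEstimate(event_times=distinct, survival=surv)


def _logrank_arrays(times, events, in_group_b) -> tuple[float, float, float]:
    """Observed events, expectation and variance for group B over pooled risk sets."""
    t, e, g = times, events, in_group_b
    distinct = np.unique(t[e == 1])
    t_sorted_all = np.sort(t)
    t_sorted_b = np.sort(t[g])
    n_all = t.size - np.searchsorted(t_sorted_all, distinct, side="left")
    n_b = int(g.sum()) - np.searchsorted(t_sorted_b, distinct, side="left")
    # events at each distinct time, overall and in group B
    d_all = np.array([int(((t == u) & (e == 1)).sum()) for u in distinct])
    d_b = np.array([int(((t == u) & (e == 1) & g).sum()) for u in distinct])
    expected = d_all * n_b / n_all
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d_all * (n_b / n_all) * (1 - n_b / n_all) * (n_all - d_all) / (n_all - 1)
    var = np.where(n_all > 1, var, 0.0)
    return float(d_b.sum()), float(expected.sum()), float(var.sum())


def logrank_test(group_assignments, times, events) -> LogrankResult:
    """Two-group log-rank test (1 df) on pooled risk sets at each event time."""
    t, e = _check_times_events(times, events)
    g = np.asarray(group_assignments)
    if g.shape != t.shape:
        raise ValueError("group assignments must match times in length")
    groups = np.unique(g)
    if groups.size != 2:
        raise ValueError(f"expected exactly two non-empty groups, found {groups.size}")
    in_b = g == groups[1]
    observed, expected, var = _logrank_arrays(t, e, in_b)
    if var == 0.0:
        return LogrankResult(statistic=0.0, p_value=1.0)
    chi2 = (observed - expected) ** 2 / var
    return LogrankResult(statistic=float(chi2), p_value=float(sps.chi2.sf(chi2, df=1)))


def iterative_cutoff(
    cohort: pd.DataFrame,
    min_group_fraction: float = 0.15,
    tie_rel_tol: float = 1e-9,
) -> CutoffResult:
    """Dichotomize a biomarker at the split that maximally separates survival.

    Candidate cutoffs are midpoints between consecutive distinct sorted
    biomarker values whose resulting Low (<= cutoff) and High (> cutoff)
    groups both contain at least ``min_group_fraction`` of the cohort.  The
    log-rank p is computed at every candidate and the minimizing cutoff is
    returned.  If the median split attains the minimal p (within
    ``tie_rel_tol`` relative tolerance) it is preferred and
    ``used_median_fallback`` is True; among other exact ties the smallest
    cutoff wins.

    Raises when no admissible split exists or when the cohort has no events.
    """
    for col in ("time", "event", "biomarker"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks column {col!r}")
    t, e = _check_times_events(cohort["time"], cohort["event"])
    b = cohort["biomarker"].to_numpy(dtype=float)
    if not np.isfinite(b).all():
        raise ValueError("biomarker values must be finite")
    if e.sum() == 0:
        raise ValueError("all follow-up is censored; the log-rank test is undefined")
    n = b.size
    if not (0 < min_group_fraction < 0.5):
        raise ValueError("min_group_fraction must lie in (0, 0.5)")
    min_group = int(np.ceil(min_group_fraction * n))

    b_sorted = np.sort(b)
    distinct = np.unique(b_sorted)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n_low = np.searchsorted(b_sorted, distinct[:-1], side="right")
    admissible = (n_low >= min_group) & (n - n_low >= min_group)
    if not admissible.any():
        raise ValueError(
            f"no candidate split leaves both groups with >= {min_group} patients"
        )
    mids, n_low = mids[admissible], n_low[admissible]

    p = np.empty(mids.size)
    for i, c in enumerate(mids):
        high = b > c
        observed, expected, var = _logrank_arrays(t, e, high)
        if var == 0.0:
            p[i] = 1.0
        else:
            p[i] = sps.chi2.sf((observed - expected) ** 2 / var, df=1)
    candidates = pd.DataFrame({"cutoff": mids, "n_low": n_low, "n_high": n - n_low, "p": p})

    p_min = p.min()
    tied = p <= p_min * (1.0 + tie_rel_tol) + np.finfo(float).tiny
    # the median split is the admissible candidate dividing the cohort most
    # evenly; for even n with distinct values this is the midpoint at n/2
    median_idx = int(np.argmin(np.abs(n_low - n / 2.0)))
    if tied[median_idx]:
        chosen = median_idx
        used_median = True
    else:
        chosen = int(np.flatnonzero(tied)[0])  # smallest qualifying cutoff
        used_median = False
    return CutoffResult(
        cutoff=float(mids[chosen]),
        n_low=int(n_low[chosen]),
        n_high=int(n - n_low[chosen]),
        p_values=candidates,
        chosen_p=float(p[chosen]),
        used_median_fallback=used_median,
    )
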