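"""Kaplan–Meier estimation and the Mantel–Cox log-rank test.

Both are implemented from first principles (product-limit estimator with
Greenwood variance; observed-minus-expected log-rank with hypergeometric
variance and a chi-square(1) reference) so they can be audited against
brute-force risk-set recomputations and cross-checked against independent
implementations.

Tie convention: deaths precede censorings at equal times, i.e. a subject
censored at t is still at risk for deaths occurring at t.  The median is
the first event time at which S(t) <= 0.5; if S lands exactly on 0.5 that
time is reported (which is how half-day medians arise with even n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["KaplanMeierFit", "km_estimate", "LogRankResult", "logrank_test"]


@dataclass
class KaplanMeierFit:
    """Product-limit survival estimate for one arm."""

    event_times: np.ndarray        # distinct death times, ascending
    survival: np.ndarray           # S(t) just after each event time
    variance: np.ndarray           # Greenwood variance of S(t)
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_subjects: int
    median: float                  # NaN when S never reaches 0.5

    def survival_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Step-function evaluation of S(t) (right-continuous)."""
        idx = np.searchsorted(self.event_times, np.asarray(t), side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return float(out) if np.isscalar(t) else out


def _validate(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be equal-length 1-D arrays")
    if np.any(t <= 0):
        raise ValueError("survival times must be > 0")
    return t, e


def km_estimate(times, events) -> KaplanMeierFit:
    """Kaplan–Meier product-limit estimator.

    Parameters
    ----------
    times : array of float
        Follow-up time per subject (days).
    events : array of bool
        True for death, False for censoring.
    """
    t, e = _validate(times, events)
    death_times = np.unique(t[e])
    surv = []
    var_terms = []
    at_risk = []
    n_ev = []
    s = 1.0
    gw = 0.0
    for dt in death_times:
        n = int(np.sum(t >= dt))          # censored at dt still at risk
        d = int(np.sum((t == dt) & e))
        s *= (n - d) / n
        if n - d > 0:
            gw += d / (n * (n - d))
        at_risk.append(n)
        n_ev.append(d)
        surv.append(s)
        var_terms.append(s**2 * gw if n - d > 0 else 0.0)
    surv = np.asarray(surv)
    below = np.nonzero(surv <= 0.5)[0]
    median = float(death_times[below[0]]) if below.size else float("nan")
    return KaplanMeierFit(
        event_times=death_times,
        survival=surv,
        variance=np.asarray(var_terms),
        n_at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_ev),
        n_subjects=t.size,
        median=median,
    )


@dataclass
class LogRankResult:
    """Mantel–Cox log-rank comparison of two arms."""

    statistic: float               # chi-square(1) statistic; NaN if undefined
    p_value: float                 # two-sided; NaN if undefined
    observed_a: float
    expected_a: float
    defined: bool


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-arm Mantel–Cox log-rank test.

    At each pooled distinct death time the observed deaths in arm A are
    compared with the expectation under the null (deaths distributed
    proportionally to the arms' risk sets); the variance is the
    hypergeometric variance.  The statistic (O-E)^2/V is referred to
    chi-square with 1 degree of freedom.  Data with zero total variance
    (e.g. a single tied death time exhausting the risk set) yield the
    ``defined=False`` sentinel rather than a spurious p-value.
    """
    ta, ea = _validate(times_a, events_a)
    tb, eb = _validate(times_b, events_b)
    if not (np.any(ea) or np.any(eb)):
        raise ValueError("log-rank requires at least one event")
    pooled = np.unique(np.concatenate([ta[ea], tb[eb]]))
    O = 0.0
    E = 0.0
    V = 0.0
    for dt in pooled:
        n1 = np.sum(ta >= dt)
        n2 = np.sum(tb >= dt)
        n = n1 + n2
        d1 = np.sum((ta == dt) & ea)
        d2 = np.sum((tb == dt) & eb)
        d = d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V <= 0:
        return LogRankResult(float("nan"), float("nan"), float(O), float(E), False)
    chi2 = (O - E) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(float(chi2), p, float(O), float(E), True)
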