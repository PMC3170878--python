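"""Responsiveness classification and the Cmax interpolation score.

A mutant is "responsive" when the chaperone produces a statistically
significant, positive increase in enzyme activity across independent
experiments (two-tailed paired t-test, P < 0.05).  The activity expected at
the clinically achievable plasma concentration (Cmax, 10 µM after a single
150 mg oral dose) is interpolated from the fitted curve parameters with the
hyperbolic (Hill slope 1) form:

    A(Cmax) = baseline + (max - baseline) * Cmax / (EC50 + Cmax)

which is bounded by [baseline, max] and works identically on the absolute
(nmol/mg/hr) and the %WT scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

DEFAULT_CMAX_UM = 10.0
DEFAULT_ALPHA = 0.05


class TTestResult(NamedTuple):
    p_value: float
    t_statistic: float
    degenerate: bool  # all paired differences exactly zero


@dataclass(frozen=True)
class ResponsivenessCall:
    responsive: bool
    p_value: float
    alpha: float
    basis: str  # "max_vs_baseline" or "cmax_vs_baseline"
    mean_increase: float
    degenerate: bool = False


def equation1_activity(
    baseline: float,
    max_activity: float,
    ec50_uM: float,
    cmax_uM: float = DEFAULT_CMAX_UM,
) -> float:
    """Interpolated activity at the clinically achievable concentration.

    Units follow the inputs (absolute activity or %WT).  ``cmax_uM=0``
    returns the baseline; ``cmax_uM == ec50_uM`` returns the midpoint of
    baseline and maximum.
    """
    if ec50_uM <= 0:
        raise ValueError("ec50_uM must be > 0")
    if cmax_uM < 0:
        raise ValueError("cmax_uM must be >= 0")
    if baseline < 0 or max_activity < 0:
        raise ValueError("activities must be >= 0")
    return baseline + (max_activity - baseline) * cmax_uM / (ec50_uM + cmax_uM)


def paired_t_two_tailed(
    baseline_values: Sequence[float], treated_values: Sequence[float]
) -> TTestResult:
    """Two-tailed paired t-test of treated vs baseline activities.

    Pairs are matched by experiment.  When every paired difference is
    exactly zero the statistic is undefined; the test is reported as
    non-significant (p = 1) with ``degenerate=True``.
    """
    b = np.asarray(baseline_values, dtype=float)
    t = np.asarray(treated_values, dtype=float)
    if b.shape != t.shape:
        raise ValueError("baseline and treated values must pair 1:1")
    if b.size < 2:
        raise ValueError("paired t-test needs >=2 experiment pairs")
    d = t - b
    if np.all(d == 0.0):
        return TTestResult(p_value=1.0, t_statistic=0.0, degenerate=True)
    with warnings.catch_warnings():
        # near-identical pairs trip scipy's precision-loss warning; the
        # resulting extreme statistic is handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_rel(t, b)
    p = float(res.pvalue)
    if not np.isfinite(p):  # zero-variance nonzero differences
        p = 0.0
    return TTestResult(p_value=p, t_statistic=float(res.statistic), degenerate=False)


def per_experiment_cmax_activities(
    summary, cmax_uM: float = DEFAULT_CMAX_UM
) -> np.ndarray:
    """Interpolated Cmax activity per experiment from its (baseline, max, EC50)."""
    return np.array(
        [
            equation1_activity(b, m, e, cmax_uM)
            for b, m, e in zip(summary.baselines, summary.maxima, summary.ec50s)
        ]
    )


def classify_responsive(
    summary,
    basis: str = "max_vs_baseline",
    alpha: float = DEFAULT_ALPHA,
    cmax_uM: float = DEFAULT_CMAX_UM,
) -> ResponsivenessCall:
    """Classify a mutant from its per-experiment values.

    ``basis="max_vs_baseline"`` tests the per-experiment maximal activities
    against the baselines (the headline responsive/non-responsive call);
    ``basis="cmax_vs_baseline"`` tests the per-experiment interpolated
    activities at Cmax instead (the call used when comparing against in-vivo
    responses at a clinically achievable concentration).  Responsive
    requires both P < alpha and a positive mean increase.
    """
    if summary.baselines is None or len(summary.baselines) < 2:
        raise ValueError("classification needs per-experiment values (n >= 2)")
    if basis == "max_vs_baseline":
        treated = np.asarray(summary.maxima, dtype=float)
    elif basis == "cmax_vs_baseline":
        treated = per_experiment_cmax_activities(summary, cmax_uM)
    else:
        raise ValueError(f"unknown basis: {basis!r}")
    baselines = np.asarray(summary.baselines, dtype=float)
    ttest = paired_t_two_tailed(baselines, treated)
    mean_increase = float(np.mean(treated - baselines))
    return ResponsivenessCall(
        responsive=bool(ttest.p_value < alpha and mean_increase > 0),
        p_value=ttest.p_value,
        alpha=alpha,
        basis=basis,
        mean_increase=mean_increase,
        degenerate=ttest.degenerate,
    )
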