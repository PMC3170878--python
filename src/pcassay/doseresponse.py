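"""Per-experiment sigmoidal concentration-response fits and aggregation.

The fitted model is

    activity(c) = baseline + (top - baseline) * c^h / (EC50^h + c^h)

with the baseline fixed to the measured 0-concentration mean (after LOQ
imputation), ``top`` and ``EC50`` free, and the Hill slope ``h`` fixed at 1
unless requested otherwise.  EC50 is optimized on the log10 scale for
stability across the 4+ decades of the dilution series.

Two reporting rules apply downstream of the fit:

* extrapolation — an EC50 above 800 µM lies beyond the reliably sampled
  range, so the reported maximum activity is the observed activity at the
  highest tested concentration rather than the fitted plateau;
* range extension — when the fitted EC50 exceeds one third of the highest
  tested concentration the curve has not clearly saturated (the top tested
  point sits below ~75% of the plateau rise) and the experiment should be
  repeated with an extended dilution series (up to 20 mM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import respond

EXTRAPOLATION_EC50_UM = 800.0

NC = None  # "not calculable" sentinel for relative increase


class AggregationError(ValueError):
    """Raised when experiment-level results cannot be aggregated."""


@dataclass(frozen=True)
class FitResult:
    """One experiment's concentration-response fit."""

    baseline: float  # nmol/mg/hr at 0 µM (fixed, LOQ-imputed measurement)
    top: float  # fitted plateau, nmol/mg/hr
    ec50_uM: float
    hill: float
    extrapolated: bool  # EC50 beyond the 800 µM reporting limit
    highest_tested_uM: float
    max_activity: float  # top, or observed activity at the highest tested c
    converged: bool
    rss: float
    n_points: int
    flat: bool = False  # all activities equal; EC50 unidentifiable
    top_below_baseline: bool = False  # monotone-decreasing data


@dataclass
class MutantSummary:
    """Across-experiment aggregate for one mutant enzyme.

    Mean ± SEM pairs mirror the dual absolute / %WT reporting of the assay;
    the per-experiment arrays are retained for paired significance testing.
    ``relative_increase_mean_sem`` is ``None`` (not calculable) when the
    baseline was imputed to zero.
    """

    variant: str
    n: int  # converged experiments aggregated
    baseline_mean_sem: tuple[float, float]
    baseline_pct_wt_mean_sem: tuple[float, float]
    max_mean_sem: tuple[float, float]
    max_pct_wt_mean_sem: tuple[float, float]
    relative_increase_mean_sem: tuple[float, float] | None
    ec50_mean_sem_uM: tuple[float, float] | None
    responsive: bool
    p_value: float
    baselines: np.ndarray = field(repr=False, default=None)
    maxima: np.ndarray = field(repr=False, default=None)
    ec50s: np.ndarray = field(repr=False, default=None)
    wt_refs: np.ndarray = field(repr=False, default=None)
    n_excluded: int = 0
    reportable: bool = True  # n >= 3 independent experiments

    @property
    def baseline_imputed_zero(self) -> bool:
        return bool(np.any(self.baselines == 0.0))


def _hill(c, baseline, top, lec50, hill):
    e = 10.0**lec50
    return baseline + (top - baseline) * c**hill / (e**hill + c**hill)


def fit_sigmoid(
    points: pd.DataFrame,
    hill_fixed: bool = True,
    extrapolation_threshold_uM: float = EXTRAPOLATION_EC50_UM,
) -> FitResult:
    """Fit one experiment's activity-vs-concentration curve.

    ``points`` needs columns ``concentration_uM`` and ``activity_nmol_mg_hr``
    including a 0-concentration row (which fixes the baseline) and at least
    four distinct nonzero concentrations.  Non-convergence is reported via
    ``converged=False``, never raised; exactly flat data (every activity
    equal) leaves the EC50 unidentifiable and is reported unconverged with
    ``flat=True``.
    """
    conc = points["concentration_uM"].to_numpy(dtype=float)
    act = points["activity_nmol_mg_hr"].to_numpy(dtype=float)
    zero = conc == 0.0
    if not zero.any():
        raise ValueError("fit requires a 0-concentration (vehicle) group")
    c = conc[~zero]
    y = act[~zero]
    if len(np.unique(c)) < 4:
        raise ValueError("fit requires >=4 distinct nonzero concentrations")

    baseline = float(np.mean(act[zero]))
    cmax_tested = float(c.max())

    def observed_at_top() -> float:
        return float(np.mean(y[c == cmax_tested]))

    def result(top, lec50, hill, converged, rss, flat=False):
        ec50 = float(10.0**lec50)
        extrapolated = converged and ec50 > extrapolation_threshold_uM
        if converged and not extrapolated:
            max_activity = max(float(top), 0.0)
        else:
            max_activity = observed_at_top()
        return FitResult(
            baseline=baseline,
            top=float(top),
            ec50_uM=ec50,
            hill=float(hill),
            extrapolated=bool(extrapolated),
            highest_tested_uM=cmax_tested,
            max_activity=max_activity,
            converged=bool(converged),
            rss=float(rss),
            n_points=int(len(y)),
            flat=flat,
            top_below_baseline=bool(converged and top <= baseline),
        )

    if np.ptp(np.concatenate([[baseline], y])) == 0.0:
        return result(baseline, np.log10(np.sqrt(c.min() * c.max())), 1.0, False,
                      0.0, flat=True)

    lo, hi = np.log10(c.min()), np.log10(c.max())

    if hill_fixed:
        # With baseline and hill fixed the model is linear in `top` at any
        # candidate EC50, so `top` is profiled out in closed form and the
        # EC50 is found by 1-D minimization on the log10 scale: coarse grid
        # over [lo-4, hi+4], then bounded Brent refinement.  Deterministic
        # and independent of any initial guess.
        def profiled(lec50: float) -> tuple[float, float]:
            w = c / (10.0**lec50 + c)
            denom = float(np.sum(w * w))
            top = baseline + float(np.sum(w * (y - baseline))) / denom
            rss = float(np.sum((baseline + (top - baseline) * w - y) ** 2))
            return top, rss

        grid = np.linspace(lo - 4.0, hi + 4.0, 81)
        rss_grid = np.array([profiled(g)[1] for g in grid])
        k = int(np.argmin(rss_grid))
        a, b2 = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda g: profiled(g)[1], bounds=(a, b2), method="bounded",
            options={"xatol": 1e-12},
        )
        lec50 = float(res.x)
        top, rss = profiled(lec50)
        return result(top, lec50, 1.0, True, rss)

    # free Hill slope: full nonlinear fit with a retry grid over the EC50 start
    top0 = float(y.max())
    best = None
    for lec50_0 in (0.5 * (lo + hi), lo, hi):
        model = lambda cc, top, lec50, hill: _hill(cc, baseline, top, lec50, hill)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, c, y, p0=[top0, lec50_0, 1.0],
                    bounds=([-np.inf, lo - 4.0, 0.1], [np.inf, hi + 4.0, 10.0]),
                    maxfev=5000,
                )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(c, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
        if rss <= 1e-14 * float(np.sum(y**2)):  # already at numerical floor
            break

    if best is None:
        return result(top0, 0.5 * (lo + hi), 1.0, False, np.inf)
    popt, rss = best
    return result(popt[0], popt[1], float(popt[2]), True, rss)


def needs_range_extension(fit: FitResult, tested_concentrations_uM) -> bool:
    """Whether the dilution series should be extended (up to 20 mM).

    True when the fit did not converge (conservative) or the fitted EC50
    exceeds one third of the highest tested concentration, i.e. the top
    tested point reaches less than ~75% of the fitted plateau rise.
    """
    top_tested = max(float(x) for x in tested_concentrations_uM)
    if not fit.converged:
        return True
    return fit.ec50_uM > top_tested / 3.0


def relative_increase(baseline: float, max_activity: float):
    """Fold increase max/baseline, or ``None`` (NC) for a zero baseline.

    Inputs must already be LOQ-imputed; a baseline imputed to zero leaves
    the ratio not calculable.
    """
    if baseline < 0 or max_activity < 0:
        raise ValueError("activities must be >= 0")
    if baseline == 0.0:
        return NC
    return max_activity / baseline


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, sem


def summarize_experiments(
    fits: list[FitResult],
    wt_refs: list[float],
    variant: str = "",
    alpha: float = 0.05,
) -> MutantSummary:
    """Aggregate per-experiment fits into a mutant-level summary.

    Unconverged fits are excluded (counted in ``n_excluded``).  %WT values
    are computed per experiment against that experiment's untreated
    wild-type reference and then averaged; the relative increase is the mean
    of per-experiment max/baseline ratios (not the ratio of the means), and
    is not calculable whenever any experiment's baseline was imputed to
    zero.  The responsiveness call here is the headline paired t-test of
    per-experiment maxima against baselines.
    """
    if not fits:
        raise AggregationError("no fits to aggregate")
    if len(fits) != len(wt_refs):
        raise AggregationError("fits and wild-type references must pair 1:1")

    kept = [(f, w) for f, w in zip(fits, wt_refs) if f.converged]
    n_excluded = len(fits) - len(kept)
    if len(kept) < 2:
        raise AggregationError("need >=2 converged experiments to summarize")

    baselines = np.array([f.baseline for f, _ in kept])
    maxima = np.array([f.max_activity for f, _ in kept])
    ec50s = np.array([f.ec50_uM for f, _ in kept])
    refs = np.array([w for _, w in kept], dtype=float)

    ratios = (
        None
        if np.any(baselines == 0.0)
        else maxima / baselines
    )

    ttest = respond.paired_t_two_tailed(baselines, maxima)
    responsive = bool(ttest.p_value < alpha and np.mean(maxima - baselines) > 0)

    return MutantSummary(
        variant=variant,
        n=len(kept),
        baseline_mean_sem=_mean_sem(baselines),
        baseline_pct_wt_mean_sem=_mean_sem(100.0 * baselines / refs),
        max_mean_sem=_mean_sem(maxima),
        max_pct_wt_mean_sem=_mean_sem(100.0 * maxima / refs),
        relative_increase_mean_sem=None if ratios is None else _mean_sem(ratios),
        ec50_mean_sem_uM=_mean_sem(ec50s) if responsive else None,
        responsive=responsive,
        p_value=ttest.p_value,
        baselines=baselines,
        maxima=maxima,
        ec50s=ec50s,
        wt_refs=refs,
        n_excluded=n_excluded,
        reportable=len(kept) >= 3,
    )
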