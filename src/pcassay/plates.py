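"""Raw plate fluorescence → calibrated, normalized enzyme activities.

The processing chain per experiment:

1. fit the 4-MU standard curve (OLS of counts on known nmol);
2. average replicate raw counts per concentration and role, and subtract the
   vector-only (endogenous background) mean at the matching concentration;
3. convert specific counts to absolute activity in nmol 4-MU released per mg
   protein per hr using the standard-curve slope (the shared plate blank
   cancels in the background subtraction, so the intercept is not applied
   again);
4. impute activities strictly below the limit of quantification (LOQ,
   default 300 nmol/mg/hr) to zero;
5. normalize to the untreated wild-type activity of the same experiment
   (% WT).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_LOQ = 300.0  # nmol 4-MU/mg protein/hr

ACTIVITY_COLUMNS = [
    "experiment_id",
    "role",
    "concentration_uM",
    "activity_nmol_mg_hr",
    "pct_wt",
    "below_loq",
]


class CalibrationError(ValueError):
    """Raised when a standard curve cannot be fitted."""


class PairingError(ValueError):
    """Raised when background subtraction pairs mismatched concentrations."""


class LOQDerivationError(ValueError):
    """Raised when vector-well replication is insufficient to derive an LOQ."""


@dataclass(frozen=True)
class StandardCurveFit:
    """Affine 4-MU calibration: counts = slope * nmol + intercept."""

    slope: float  # counts per nmol 4-MU
    intercept: float  # counts
    r_squared: float


@dataclass(frozen=True)
class ActivityPoint:
    """Background-subtracted, calibrated, protein-normalized activity."""

    experiment_id: int
    concentration_uM: float
    activity: float  # nmol 4-MU/mg protein/hr, LOQ-imputed
    below_loq: bool


def fit_standard_curve(standard_wells: pd.DataFrame) -> StandardCurveFit:
    """OLS fit of raw fluorescence on known 4-MU amount.

    ``standard_wells`` needs columns ``known_4mu_nmol`` and
    ``raw_fluorescence`` with at least three distinct amounts.
    """
    nmol = np.asarray(standard_wells["known_4mu_nmol"], dtype=float)
    counts = np.asarray(standard_wells["raw_fluorescence"], dtype=float)
    if len(np.unique(nmol)) < 3:
        raise CalibrationError("standard curve needs >=3 distinct 4-MU amounts")
    res = stats.linregress(nmol, counts)
    if not np.isfinite(res.slope) or res.slope <= 0:
        raise CalibrationError(f"degenerate standard curve (slope={res.slope})")
    return StandardCurveFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def subtract_background(test_counts: float, vector_counts: float, *,
                        test_concentration_uM: float | None = None,
                        vector_concentration_uM: float | None = None) -> float:
    """Specific counts: test-well mean minus vector-only mean, floored at 0.

    Both means must come from the same chaperone concentration of the same
    experiment; pass the concentrations to enforce the pairing.
    """
    if (
        test_concentration_uM is not None
        and vector_concentration_uM is not None
        and test_concentration_uM != vector_concentration_uM
    ):
        raise PairingError(
            f"background pairing mismatch: test at {test_concentration_uM} µM, "
            f"vector at {vector_concentration_uM} µM"
        )
    return max(float(test_counts) - float(vector_counts), 0.0)


def compute_activity(
    specific_counts: float,
    calib: StandardCurveFit,
    protein_mg: float,
    incubation_hr: float = 1.0,
) -> float:
    """Absolute activity in nmol 4-MU/mg protein/hr.

    The calibration intercept is not re-subtracted: the shared plate blank
    is already removed by the vector-well background subtraction.
    """
    if protein_mg <= 0:
        raise ValueError("protein_mg must be > 0")
    if incubation_hr <= 0:
        raise ValueError("incubation_hr must be > 0")
    return (float(specific_counts) / calib.slope) / protein_mg / incubation_hr


def derive_loq(vector_activity_sets: Iterable[Sequence[float]]) -> float:
    """Empirical limit of quantification from vector-only well activities.

    Returns the smallest L such that L >= 1.645*SD_e (SD of the vector-well
    activities of experiment e) in at least 90% of experiments — i.e. the
    ceil(0.9 n)-th order statistic of {1.645*SD_e}.
    """
    sds = []
    for values in vector_activity_sets:
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise LOQDerivationError("each experiment needs >=2 vector wells")
        sds.append(1.645 * float(np.std(arr, ddof=1)))
    if len(sds) < 2:
        raise LOQDerivationError("need >=2 experiments to derive an LOQ")
    sds.sort()
    k = int(np.ceil(0.9 * len(sds)))
    return sds[k - 1]


def apply_loq(activity: float, loq: float = DEFAULT_LOQ) -> tuple[float, bool]:
    """Impute activities strictly below the LOQ to zero.

    Returns ``(value, below_loq)``; values exactly at the LOQ are kept.
    Idempotent: re-applying to an imputed zero returns zero again.
    """
    if loq <= 0:
        raise ValueError("loq must be > 0")
    if activity < 0:
        raise ValueError("activity must be >= 0 (upstream flooring violated)")
    if activity < loq:
        return 0.0, True
    return float(activity), False


def normalize_to_wt(activity: float, wt_untreated_activity: float) -> float:
    """Activity as percent of the untreated wild-type reference."""
    if wt_untreated_activity <= 0:
        raise ValueError("wild-type reference activity must be > 0")
    return 100.0 * float(activity) / float(wt_untreated_activity)


def vector_well_activities(wells: pd.DataFrame, incubation_hr: float = 1.0) -> list[np.ndarray]:
    """Per-experiment arrays of individual vector-well activities.

    Used to derive the empirical LOQ.  Each well is calibrated on its own
    experiment's standard curve with the fitted blank (intercept) removed,
    since no background subtraction applies to the background wells
    themselves.
    """
    out = []
    for _, exp in wells.groupby("experiment_id", sort=True):
        calib = fit_standard_curve(exp[exp["role"] == "standard"])
        vec = exp[exp["role"] == "vector"]
        counts = vec["raw_fluorescence"].to_numpy(dtype=float)
        protein = vec["protein_mg"].to_numpy(dtype=float)
        act = np.maximum(counts - calib.intercept, 0.0) / calib.slope / protein / incubation_hr
        out.append(act)
    return out


def _process_one_experiment(
    exp: pd.DataFrame, loq: float, incubation_hr: float
) -> pd.DataFrame:
    exp_id = int(exp["experiment_id"].iloc[0])
    calib = fit_standard_curve(exp[exp["role"] == "standard"])

    lysate = exp[exp["role"] != "standard"]
    grouped = lysate.groupby(["role", "concentration_uM"], sort=True).agg(
        counts=("raw_fluorescence", "mean"), protein=("protein_mg", "mean")
    )
    vector = grouped.loc["vector"] if "vector" in grouped.index.get_level_values(0) else None

    rows = []
    for role in ("mutant", "wildtype"):
        if role not in grouped.index.get_level_values(0):
            continue
        sub = grouped.loc[role]
        for conc, row in sub.iterrows():
            if vector is not None:
                if conc not in vector.index:
                    raise PairingError(
                        f"no vector wells at {conc} µM in experiment {exp_id}"
                    )
                specific = subtract_background(
                    row["counts"],
                    vector.loc[conc, "counts"],
                    test_concentration_uM=conc,
                    vector_concentration_uM=conc,
                )
            else:
                specific = max(float(row["counts"]), 0.0)
            activity = compute_activity(specific, calib, row["protein"], incubation_hr)
            value, below = apply_loq(activity, loq)
            rows.append((exp_id, role, float(conc), value, below))

    out = pd.DataFrame(
        rows,
        columns=["experiment_id", "role", "concentration_uM", "activity_nmol_mg_hr", "below_loq"],
    )
    wt0 = out[(out["role"] == "wildtype") & (out["concentration_uM"] == 0.0)]
    if len(wt0) and wt0["activity_nmol_mg_hr"].iloc[0] > 0:
        wt_ref = float(wt0["activity_nmol_mg_hr"].iloc[0])
        out["pct_wt"] = 100.0 * out["activity_nmol_mg_hr"] / wt_ref
    else:
        out["pct_wt"] = np.nan
    return out[ACTIVITY_COLUMNS]


def process_wells(
    wells: pd.DataFrame, loq: float = DEFAULT_LOQ, incubation_hr: float = 1.0
) -> pd.DataFrame:
    """Process a tidy well table into per-concentration activities.

    Input columns are those written by the synthetic-assay generator
    (``experiment_id, role, concentration_uM, replicate, raw_fluorescence,
    protein_mg, known_4mu_nmol``).  Output: one row per experiment × role
    (mutant/wildtype) × concentration with the LOQ-imputed absolute activity
    and the same-experiment %WT, where the %WT reference is the untreated
    wild-type mean of that experiment.
    """
    parts = [
        _process_one_experiment(exp, loq, incubation_hr)
        for _, exp in wells.groupby("experiment_id", sort=True)
    ]
    return pd.concat(parts, ignore_index=True)
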