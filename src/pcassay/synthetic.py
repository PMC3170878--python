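"""Seeded generator of raw chaperone-assay plate data.

Emulates the transient-transfection HEK-293 assay: each simulated experiment
holds quadruplicate mutant-, vector-only- and wild-type-transfected wells at
a 3-fold chaperone dilution series (50 nM - 1 mM by default, extendable),
plus a 4-MU standard-curve dilution series, all expressed as raw
fluorescence counts with total protein per well.

Generative model
----------------
Expressed mutant activity at chaperone concentration ``c`` follows a Hill
curve,

    a(c) = W * [ b + (t - b) * c^h / (E^h + c^h) ]

with ``W`` the absolute wild-type activity, ``b``/``t`` the baseline/plateau
fractions of wild-type, ``E`` the EC50 and ``h`` the Hill slope (1 by
default, matching the hyperbolic form the downstream Cmax score assumes).
Vector-only wells carry only the endogenous HEK-293 background; wild-type
wells carry endogenous plus ``W`` and are non-responsive to the chaperone by
default (transient overexpression saturates the folding machinery, so the
transfected wild-type control shows no consistent concentration response; a
switch makes the endogenous background responsive instead).  Well
fluorescence is ``blank + gain * nmol 4-MU released``, with multiplicative
log-normal well noise of a given CV and a per-experiment log-normal scale
factor on all biological activities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AssayDesign",
    "TrueMutantProfile",
    "default_concentrations",
    "default_standard_amounts",
    "hill_curve",
    "simulate_assay",
    "simulate_experiment",
    "simulate_pbmc_course",
    "simulate_standard_curve",
]

WELL_COLUMNS = [
    "experiment_id",
    "role",
    "concentration_uM",
    "replicate",
    "raw_fluorescence",
    "protein_mg",
    "known_4mu_nmol",
]


class DesignError(ValueError):
    """Raised for invalid generator profiles or assay designs."""


def hill_curve(
    c: np.ndarray | float,
    baseline: float,
    top: float,
    ec50: float,
    hill: float = 1.0,
) -> np.ndarray | float:
    """Hill concentration-response curve ``baseline + (top-baseline)*c^h/(E^h+c^h)``."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(c > 0, c**hill / (ec50**hill + c**hill), 0.0)
    out = baseline + (top - baseline) * frac
    return float(out) if out.ndim == 0 else out


def default_concentrations(top_uM: float = 1000.0, n_dilutions: int = 10) -> list[float]:
    """Chaperone 3-fold dilution series (ascending), plus the 0 control.

    The default spans 50 nM to 1 mM; pass ``top_uM=20000`` for the extended
    range used when a curve does not saturate below 1 mM.
    """
    series = [top_uM / 3.0**k for k in range(n_dilutions)]
    return [0.0] + sorted(series)


def default_standard_amounts(
    top_nmol: float = 3.6, n_dilutions: int = 11, ratio: float = 3.0
) -> list[float]:
    """4-MU standard-curve amounts (nmol/well), 3-fold dilutions.

    3.6 nmol corresponds to 30 µM 4-MU in a 120 µl final reaction volume;
    eleven 3-fold dilutions reach the low-nanomolar end of the calibration
    range (~1.3 nM).
    """
    return sorted(top_nmol / ratio**k for k in range(n_dilutions))


@dataclass(frozen=True)
class TrueMutantProfile:
    """Ground-truth response parameters of one simulated mutant enzyme.

    ``baseline_frac`` and ``top_frac`` are fractions of wild-type activity at
    zero and saturating chaperone; ``catalytically_active=False`` forces zero
    expressed activity at every concentration regardless of ``top_frac``
    (emulating mutants that bind the chaperone and accumulate protein but
    cannot turn over substrate).
    """

    name: str
    baseline_frac: float
    top_frac: float
    ec50_uM: float
    hill: float = 1.0
    catalytically_active: bool = True

    def __post_init__(self) -> None:
        if self.baseline_frac < 0:
            raise DesignError("baseline_frac must be >= 0")
        if self.catalytically_active and self.top_frac < self.baseline_frac:
            raise DesignError("top_frac must be >= baseline_frac for an active enzyme")
        if self.ec50_uM <= 0:
            raise DesignError("ec50_uM must be > 0")
        if self.hill <= 0:
            raise DesignError("hill must be > 0")

    def expressed_activity(self, c: np.ndarray | float, wt_activity: float):
        """Expected expressed activity (nmol/mg/hr) at concentration(s) ``c``."""
        if not self.catalytically_active:
            return np.zeros_like(np.asarray(c, dtype=float))
        return wt_activity * hill_curve(
            c, self.baseline_frac, self.top_frac, self.ec50_uM, self.hill
        )


@dataclass(frozen=True)
class AssayDesign:
    """Plate layout, scale and noise parameters of the simulated assay."""

    concentrations_uM: tuple[float, ...] = tuple(default_concentrations())
    n_replicates: int = 4
    n_experiments: int = 3
    wt_activity: float = 33000.0  # nmol/mg/hr, order of the transfected wild-type
    endogenous_frac: float = 0.02  # vector-only background as fraction of wt_activity
    endogenous_responsive: bool = False
    endogenous_top_frac: float = 0.05
    endogenous_ec50_uM: float = 20.0
    wt_responsive: bool = False  # transfected wild-type control responds if True
    wt_top_factor: float = 1.17
    protein_mg_per_well: float = 0.01
    fluor_per_nmol: float = 1000.0  # calibration gain, counts per nmol 4-MU
    fluor_blank: float = 50.0  # shared plate blank, counts
    standard_amounts_nmol: tuple[float, ...] = tuple(default_standard_amounts())
    noise_cv: float = 0.10
    between_experiment_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if 0.0 not in self.concentrations_uM:
            raise DesignError("concentrations must include the 0 (vehicle) control")
        if self.n_replicates < 1:
            raise DesignError("n_replicates must be >= 1")
        if self.fluor_per_nmol <= 0:
            raise DesignError("fluor_per_nmol (calibration gain) must be > 0")
        if min(self.noise_cv, self.between_experiment_cv) < 0:
            raise DesignError("noise CVs must be >= 0")
        if self.protein_mg_per_well <= 0:
            raise DesignError("protein_mg_per_well must be > 0")

    def endogenous_activity(self, c: np.ndarray | float):
        """Vector-only background activity (nmol/mg/hr) vs concentration."""
        base = self.endogenous_frac * self.wt_activity
        if not self.endogenous_responsive:
            return base * np.ones_like(np.asarray(c, dtype=float))
        top = self.endogenous_top_frac * self.wt_activity
        return hill_curve(c, base, top, self.endogenous_ec50_uM)

    def with_(self, **changes) -> "AssayDesign":
        return replace(self, **changes)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with mean exactly 1 and CV exactly ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _experiment_rng(seed: int, experiment_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, experiment_id)))


def experiment_scale(design: AssayDesign, experiment_id: int) -> float:
    """The latent between-experiment scale factor of one experiment.

    Reproduces the draw made by :func:`simulate_experiment` so recovery
    tests can compare fitted parameters against the scaled truth of each
    experiment rather than the population-level curve.
    """
    rng = _experiment_rng(design.seed, experiment_id)
    return float(_lognormal_factors(rng, design.between_experiment_cv, ()))


def simulate_standard_curve(
    design: AssayDesign, seed: int | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate the 4-MU calibration series of one plate.

    Expected fluorescence is affine in the known 4-MU amount
    (``blank + gain * nmol``) with multiplicative well noise on the signal.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    amounts = np.asarray(design.standard_amounts_nmol, dtype=float)
    noise = _lognormal_factors(rng, design.noise_cv, amounts.shape)
    counts = design.fluor_blank + design.fluor_per_nmol * amounts * noise
    return pd.DataFrame({"known_4mu_nmol": amounts, "raw_fluorescence": counts})


def simulate_experiment(
    profile: TrueMutantProfile, design: AssayDesign, experiment_id: int
) -> pd.DataFrame:
    """Simulate every well of one independent experiment.

    Returns a tidy table (one row per well) with columns
    ``experiment_id, role, concentration_uM, replicate, raw_fluorescence,
    protein_mg, known_4mu_nmol``.  Roles are ``mutant``, ``vector``,
    ``wildtype`` and ``standard``; the standard-curve rows leave
    concentration and protein unset.
    """
    rng = _experiment_rng(design.seed, experiment_id)
    scale = float(_lognormal_factors(rng, design.between_experiment_cv, ()))

    concs = np.asarray(sorted(design.concentrations_uM), dtype=float)
    reps = design.n_replicates

    endo = np.asarray(design.endogenous_activity(concs), dtype=float)
    expressed = np.asarray(profile.expressed_activity(concs, design.wt_activity), dtype=float)
    if design.wt_responsive:
        wt_expr = design.wt_activity * hill_curve(
            concs, 1.0, design.wt_top_factor, design.endogenous_ec50_uM
        )
    else:
        wt_expr = design.wt_activity * np.ones_like(concs)

    role_activity = {
        "mutant": endo + expressed,
        "vector": endo,
        "wildtype": endo + wt_expr,
    }

    frames = []
    protein = design.protein_mg_per_well
    for role, activity in role_activity.items():
        per_well = np.repeat(activity * scale, reps)  # nmol/mg/hr expected
        nmol = per_well * protein  # 1 hr incubation
        noise = _lognormal_factors(rng, design.noise_cv, per_well.shape)
        counts = design.fluor_blank + design.fluor_per_nmol * nmol * noise
        frames.append(
            pd.DataFrame(
                {
                    "experiment_id": experiment_id,
                    "role": role,
                    "concentration_uM": np.repeat(concs, reps),
                    "replicate": np.tile(np.arange(1, reps + 1), concs.size),
                    "raw_fluorescence": counts,
                    "protein_mg": protein,
                    "known_4mu_nmol": np.nan,
                }
            )
        )

    std = simulate_standard_curve(design, rng=rng)
    frames.append(
        pd.DataFrame(
            {
                "experiment_id": experiment_id,
                "role": "standard",
                "concentration_uM": np.nan,
                "replicate": np.arange(1, len(std) + 1),
                "raw_fluorescence": std["raw_fluorescence"].to_numpy(),
                "protein_mg": np.nan,
                "known_4mu_nmol": std["known_4mu_nmol"].to_numpy(),
            }
        )
    )
    return pd.concat(frames, ignore_index=True)[WELL_COLUMNS]


def simulate_assay(
    profile: TrueMutantProfile, design: AssayDesign
) -> tuple[pd.DataFrame, dict]:
    """Simulate ``design.n_experiments`` independent experiments.

    Returns the concatenated well table and a truth sidecar (ground-truth
    parameters on the absolute activity scale) for recovery tests.
    """
    wells = pd.concat(
        [simulate_experiment(profile, design, i) for i in range(1, design.n_experiments + 1)],
        ignore_index=True,
    )
    truth = {
        "name": profile.name,
        "baseline_nmol_mg_hr": profile.baseline_frac * design.wt_activity
        if profile.catalytically_active
        else 0.0,
        "top_nmol_mg_hr": profile.top_frac * design.wt_activity
        if profile.catalytically_active
        else 0.0,
        "ec50_uM": profile.ec50_uM,
        "hill": profile.hill,
        "catalytically_active": profile.catalytically_active,
        "wt_activity_nmol_mg_hr": design.wt_activity,
        "seed": design.seed,
        "n_experiments": design.n_experiments,
        "experiment_scales": [
            experiment_scale(design, i) for i in range(1, design.n_experiments + 1)
        ],
    }
    return wells, truth


def simulate_pbmc_course(
    baseline_pct_normal: float,
    treated_pct_normal: float,
    timepoints: list[str],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Simulate an in-vivo PBMC activity course (% of normal).

    Returns a predose "baseline" entry centred at ``baseline_pct_normal``
    followed by one entry per post-dose timepoint centred at
    ``treated_pct_normal``, with multiplicative log-normal noise of the
    given CV.
    """
    if not timepoints:
        raise DesignError("timepoints must be non-empty")
    if baseline_pct_normal < 0 or treated_pct_normal < 0:
        raise DesignError("activities must be >= 0")
    rng = np.random.default_rng(seed)
    labels = ["baseline", *timepoints]
    levels = np.full(len(labels), treated_pct_normal, dtype=float)
    levels[0] = baseline_pct_normal
    values = levels * _lognormal_factors(rng, noise_cv, levels.shape)
    return list(zip(labels, values.tolist()))
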