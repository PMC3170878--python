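"""Pipeline configuration.

Every threshold used by the analysis is a config field rather than a code
literal: the activity limit of quantification (LOQ), the significance level
of the paired t-test, the clinically achievable chaperone concentration
(Cmax), the PBMC good-responder threshold, and the healthy-volunteer PBMC
reference activity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and switches for the responsiveness pipeline.

    Parameters
    ----------
    loq_nmol_mg_hr
        Limit of quantification for α-Gal A activity; measured or calculated
        activities strictly below it are imputed to zero (nmol 4-MU/mg
        protein/hr).
    alpha
        Two-sided significance level of the paired t-test used for the
        responsive/non-responsive call.
    cmax_uM
        Clinically achievable plasma concentration of the chaperone at which
        activity is scored (µM).
    responder_threshold_pct_normal
        Minimal net increase in PBMC activity (% of normal) that defines a
        "good" in-vivo responder.
    normal_pbmc_activity_nmol_mg_hr
        Mean α-Gal A activity in PBMCs of healthy volunteers, the reference
        for %-of-normal conversion.
    hill_fixed
        Fit concentration-response curves with Hill slope fixed at 1
        (the form used by the Cmax interpolation score).
    seed
        Seed for any synthetic-data generation launched by the pipeline.
    """

    loq_nmol_mg_hr: float = 300.0
    alpha: float = 0.05
    cmax_uM: float = 10.0
    responder_threshold_pct_normal: float = 3.0
    normal_pbmc_activity_nmol_mg_hr: float = 22.0
    hill_fixed: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "loq_nmol_mg_hr",
            "alpha",
            "cmax_uM",
            "responder_threshold_pct_normal",
            "normal_pbmc_activity_nmol_mg_hr",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def asdict(self) -> dict:
        return dataclasses.asdict(self)
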