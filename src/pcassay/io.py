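"""Fixture loaders, table I/O and pipeline orchestration.

The packaged fixtures transcribe the two published result tables of the
HEK-293 chaperone-response study:

* ``table1.tsv`` — 81 mutant α-Gal A forms plus the wild-type control:
  baseline and maximal activities (absolute and %WT, mean ± SEM), relative
  increase, EC50 and the number of independent experiments.  Sentinels are
  preserved verbatim ("NC" = not calculable, "—" = no significant response)
  and parsed to typed missing markers on load.
* ``table2.tsv`` — 22 treated subjects (19 distinct mutant forms) with
  cell-based %WT values at 0 and 10 µM chaperone, the cell-based call, and
  the in-vivo PBMC activity course (% of normal; ND/NA = missing).

Loaders validate row counts and a stored checksum so silent fixture edits
fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import doseresponse, plates, respond
from .concord import GOOD, NON_LIMITED, PbmcMeasurement, SubjectRecord
from .config import PipelineConfig
from .synthetic import WELL_COLUMNS
from .variants import parse_variant

TABLE1_SHA256 = "2e29eb931d2669fb617d3d628e686de4368c54365af01fd29787f70587e463c1"
TABLE2_SHA256 = "c287095ecebbc870a1e1ce976770135e032390c7ef4119a450ee12c88fbd8cd1"
N_TABLE1_MUTANTS = 81
N_TABLE2_SUBJECTS = 22
N_TABLE2_VARIANTS = 19

_MISSING = {"—", "-", ""}


class FixtureIntegrityError(RuntimeError):
    """Raised when a packaged fixture fails its checksum or row-count check."""


def _fixture_text(name: str) -> str:
    return resources.files("pcassay.data").joinpath(name).read_text()


def _check(name: str, text: str, expected_sha: str) -> None:
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != expected_sha:
        raise FixtureIntegrityError(f"{name}: checksum mismatch ({digest})")


def _num(token: str) -> float | None:
    token = token.strip()
    if token in _MISSING or token == "NC":
        return None
    return float(token)


def load_table1_fixture(validate: bool = True) -> pd.DataFrame:
    """Load the mutant-panel fixture as a typed DataFrame.

    Numeric columns hold NaN where the table prints a sentinel;
    ``relative_increase_nc`` marks "NC" entries, ``responsive`` is derived
    from EC50 presence (the table reports an EC50 exactly for the mutant
    forms with a significant response), and ``extrapolated`` flags EC50
    values beyond 800 µM, for which the reported maximum is the observed
    activity at the highest tested concentration.
    """
    from io import StringIO

    text = _fixture_text("table1.tsv")
    if validate:
        _check("table1.tsv", text, TABLE1_SHA256)
    raw = pd.read_csv(StringIO(text), sep="\t", dtype=str, keep_default_na=False)

    df = pd.DataFrame(
        {
            "protein_change": raw["protein_change"],
            "cdna_change": raw["cdna_change"],
        }
    )
    for col in (
        "baseline_activity",
        "baseline_sem",
        "baseline_pct_wt",
        "baseline_pct_wt_sem",
        "max_activity",
        "max_sem",
        "max_pct_wt",
        "max_pct_wt_sem",
        "relative_increase",
        "relative_increase_sem",
        "ec50_uM",
        "ec50_sem_uM",
    ):
        df[col] = [_num(v) for v in raw[col]]
    df["relative_increase_nc"] = raw["relative_increase"].str.strip() == "NC"
    df["significance"] = raw["significance"].str.strip()
    df["high_range"] = raw["high_range"].str.strip() == "yes"
    df["n"] = raw["n"].astype(int)
    df["is_wildtype"] = df["protein_change"] == "Wild-type"
    df["responsive"] = df["ec50_uM"].notna() & ~df["is_wildtype"]
    df["extrapolated"] = df["ec50_uM"] > doseresponse.EXTRAPOLATION_EC50_UM

    if validate:
        mutants = df[~df["is_wildtype"]]
        if len(mutants) != N_TABLE1_MUTANTS:
            raise FixtureIntegrityError(
                f"table1.tsv: expected {N_TABLE1_MUTANTS} mutant rows, got {len(mutants)}"
            )
        if not df["is_wildtype"].any():
            raise FixtureIntegrityError("table1.tsv: wild-type row missing")
        if int(mutants["responsive"].sum()) != 49:
            raise FixtureIntegrityError("table1.tsv: responsive row count != 49")
        for _, row in mutants.iterrows():
            parse_variant(row["protein_change"], row["cdna_change"])
    return df


def _parse_posts(labels: str, doses: str, values: str) -> tuple[PbmcMeasurement, ...]:
    out = []
    for label, dose, value in zip(labels.split("|"), doses.split("|"), values.split("|")):
        v = value.strip()
        pct = None if v in {"ND", "NA"} else float(v)
        out.append(PbmcMeasurement(timepoint=label.strip(), pct_normal=pct, dose=dose.strip()))
    return tuple(out)


def load_table2_fixture(validate: bool = True) -> list[SubjectRecord]:
    """Load the clinical-comparison fixture as typed subject records."""
    from io import StringIO

    text = _fixture_text("table2.tsv")
    if validate:
        _check("table2.tsv", text, TABLE2_SHA256)
    raw = pd.read_csv(StringIO(text), sep="\t", dtype=str, keep_default_na=False)

    subjects = []
    for _, row in raw.iterrows():
        subjects.append(
            SubjectRecord(
                subject_id=int(row["subject_id"]),
                study=row["study"],
                protein_change=row["protein_change"],
                cdna_change=row["cdna_change"],
                hek_baseline_pct_wt=float(row["hek_baseline_pct_wt"]),
                hek_cmax_pct_wt=float(row["hek_cmax_pct_wt"]),
                hek_responsive_at_cmax=row["hek_responsive"].strip() == "Yes",
                pbmc_baseline_pct_normal=float(row["pbmc_baseline_pct_normal"]),
                pbmc_post=_parse_posts(
                    row["post_labels"], row["post_doses"], row["post_values"]
                ),
                category=GOOD if row["category"].strip() == "Good" else NON_LIMITED,
            )
        )
    if validate:
        if len(subjects) != N_TABLE2_SUBJECTS:
            raise FixtureIntegrityError(
                f"table2.tsv: expected {N_TABLE2_SUBJECTS} subjects, got {len(subjects)}"
            )
        n_variants = len({s.protein_change for s in subjects})
        if n_variants != N_TABLE2_VARIANTS:
            raise FixtureIntegrityError(
                f"table2.tsv: expected {N_TABLE2_VARIANTS} distinct variants, got {n_variants}"
            )
    return subjects


# ---------------------------------------------------------------------------
# Well / activity table I/O


def write_wells(wells: pd.DataFrame, path: str | Path) -> None:
    wells.to_csv(path, sep="\t", index=False)


def read_wells(path: str | Path) -> pd.DataFrame:
    wells = pd.read_csv(path, sep="\t")
    missing = set(WELL_COLUMNS) - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")
    return wells


def write_activities(activities: pd.DataFrame, path: str | Path) -> None:
    activities.to_csv(path, sep="\t", index=False)


def read_activities(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(
    config: PipelineConfig,
    wells: pd.DataFrame,
    variant: str = "",
    out_dir: str | Path | None = None,
) -> dict:
    """Run process → fit → classify on one mutant's well table.

    Returns a bundle with the activity table, per-experiment fits, the
    across-experiment summary and the responsiveness calls on both bases;
    when ``out_dir`` is given, writes the activity table, a summary TSV and
    a JSON manifest recording the configuration for reproducibility.
    """
    activities = plates.process_wells(wells, loq=config.loq_nmol_mg_hr)

    fits, wt_refs = [], []
    for exp_id, exp in activities.groupby("experiment_id", sort=True):
        mut = exp[exp["role"] == "mutant"]
        fits.append(fit := doseresponse.fit_sigmoid(mut, hill_fixed=config.hill_fixed))
        wt0 = exp[(exp["role"] == "wildtype") & (exp["concentration_uM"] == 0.0)]
        wt_refs.append(float(wt0["activity_nmol_mg_hr"].iloc[0]))

    summary = doseresponse.summarize_experiments(
        fits, wt_refs, variant=variant, alpha=config.alpha
    )
    call_max = respond.classify_responsive(
        summary, basis="max_vs_baseline", alpha=config.alpha, cmax_uM=config.cmax_uM
    )
    call_cmax = respond.classify_responsive(
        summary, basis="cmax_vs_baseline", alpha=config.alpha, cmax_uM=config.cmax_uM
    )
    eq1_pct_wt = respond.equation1_activity(
        summary.baseline_pct_wt_mean_sem[0],
        summary.max_pct_wt_mean_sem[0],
        summary.ec50_mean_sem_uM[0] if summary.ec50_mean_sem_uM else np.inf,
        config.cmax_uM,
    ) if summary.ec50_mean_sem_uM else summary.baseline_pct_wt_mean_sem[0]

    bundle = {
        "activities": activities,
        "fits": fits,
        "summary": summary,
        "call_max": call_max,
        "call_cmax": call_cmax,
        "activity_at_cmax_pct_wt": eq1_pct_wt,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_activities(activities, out / "activities.tsv")
        manifest = {
            "config": config.asdict(),
            "variant": variant,
            "n_experiments": summary.n,
            "n_excluded": summary.n_excluded,
            "responsive_max_basis": call_max.responsive,
            "responsive_cmax_basis": call_cmax.responsive,
            "p_value_max_basis": call_max.p_value,
            "p_value_cmax_basis": call_cmax.p_value,
            "activity_at_cmax_pct_wt": eq1_pct_wt,
            "summary": {
                "baseline_mean_sem": summary.baseline_mean_sem,
                "max_mean_sem": summary.max_mean_sem,
                "ec50_mean_sem_uM": summary.ec50_mean_sem_uM,
                "relative_increase_mean_sem": summary.relative_increase_mean_sem,
            },
            "fits": [dataclasses.asdict(f) for f in fits],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return bundle
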