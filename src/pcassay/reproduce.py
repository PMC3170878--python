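"""Fixture-based reproduction of the published panel results.

Every check recomputes a published quantity from the packaged table
fixtures through the package's own operations: response counts from the
mutant panel, interpolated activities at the clinically achievable
concentration, concordance statistics against the lymphoblast and in-vivo
PBMC comparisons, and the cross-assay Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import concord, respond
from .io import load_table1_fixture, load_table2_fixture


@dataclass(frozen=True)
class Check:
    name: str
    expected: float
    observed: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.observed - self.expected) <= self.tolerance


def panel_counts(table1: pd.DataFrame | None = None) -> dict[str, int]:
    """Responsiveness counts over the 81-mutant panel."""
    df = load_table1_fixture() if table1 is None else table1
    mutants = df[~df["is_wildtype"]]
    responsive = mutants["responsive"]
    zero_baseline = mutants["baseline_pct_wt"] == 0.0
    return {
        "n_mutants": int(len(mutants)),
        "n_responsive": int(responsive.sum()),
        "n_zero_baseline": int(zero_baseline.sum()),
        "n_zero_baseline_responsive": int((responsive & zero_baseline).sum()),
        "n_quantifiable_baseline_responsive": int((responsive & ~zero_baseline).sum()),
        "n_responsive_ec50_le_10uM": int(
            (responsive & (mutants["ec50_uM"] <= 10.0)).sum()
        ),
    }


def cmax_activity_from_panel(
    protein_change: str, cmax_uM: float = 10.0, table1: pd.DataFrame | None = None
) -> float:
    """Interpolated %WT activity at Cmax from a mutant's panel parameters.

    Uses the printed baseline %WT (zero when imputed), maximum %WT and EC50
    of the given mutant.
    """
    df = load_table1_fixture() if table1 is None else table1
    row = df[df["protein_change"] == protein_change]
    if len(row) != 1:
        raise KeyError(f"variant not found in panel fixture: {protein_change}")
    row = row.iloc[0]
    if pd.isna(row["ec50_uM"]):
        raise ValueError(f"{protein_change} has no EC50 (non-responsive)")
    return respond.equation1_activity(
        baseline=float(row["baseline_pct_wt"]),
        max_activity=float(row["max_pct_wt"]),
        ec50_uM=float(row["ec50_uM"]),
        cmax_uM=cmax_uM,
    )


def run_all_checks() -> list[Check]:
    """Recompute the headline published quantities and compare."""
    table1 = load_table1_fixture()
    subjects = load_table2_fixture()
    counts = panel_counts(table1)

    checks = [
        Check("responsive mutants (of 81)", 49, counts["n_responsive"], 0),
        Check("zero-baseline mutants", 54, counts["n_zero_baseline"], 0),
        Check(
            "zero-baseline responsive", 22, counts["n_zero_baseline_responsive"], 0
        ),
        Check(
            "responsive with EC50 <= 10 uM",
            16,
            counts["n_responsive_ec50_le_10uM"],
            0,
        ),
    ]

    for variant, printed in [
        ("p.N215S", 40.7),
        ("p.M51K", 25.1),
        ("p.S276G", 3.7),
        ("p.G328A", 22.1),
    ]:
        checks.append(
            Check(
                f"activity at 10 uM, {variant} (%WT)",
                printed,
                round(cmax_activity_from_panel(variant, table1=table1), 1),
                0.2,
            )
        )

    lymph = concord.lymphoblast_concordance()
    checks.append(Check("lymphoblast sensitivity", 0.90, lymph.sensitivity_rounded, 0))
    checks.append(Check("lymphoblast specificity", 0.92, lymph.specificity_rounded, 0))

    pbmc = concord.hek_vs_pbmc_concordance(subjects)
    checks.append(Check("PBMC sensitivity", 1.0, pbmc.sensitivity_rounded, 0))
    checks.append(Check("PBMC specificity", 0.88, pbmc.specificity_rounded, 0))
    checks.append(Check("PBMC discordant mutant count", 1, len(pbmc.discordant), 0))
    checks.append(
        Check(
            "baseline correlation r (HEK vs PBMC)",
            0.639,
            pbmc.correlations["baseline"].r,
            0.05,
        )
    )
    return checks


def format_checks(checks: list[Check]) -> str:
    lines = [f"{'check':45s} {'expected':>9s} {'observed':>9s}  result"]
    for c in checks:
        lines.append(
            f"{c.name:45s} {c.expected:9.3f} {c.observed:9.3f}  "
            + ("PASS" if c.passed else "FAIL")
        )
    return "\n".join(lines)
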