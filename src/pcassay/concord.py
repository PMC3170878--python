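"""Concordance between cell-based calls and independent response data.

Two comparisons are supported:

* HEK-293 vs patient-derived lymphoblasts — confusion counts between the
  responsive/non-responsive calls of the two in-vitro assays (the published
  comparison covers 75 shared mutant forms);
* HEK-293 vs in-vivo PBMC responses — subjects dosed orally are categorized
  as "good" responders when their maximal net PBMC activity increase from
  baseline reaches at least 3% of normal, and the category is compared with
  the cell-based call at the clinically achievable concentration.

Sensitivity and specificity treat the comparator assay (lymphoblast call or
in-vivo category) as the reference and the HEK-293 call as the test.
Agreement of the underlying quantities is measured with Pearson correlation
(two-tailed p from the t transform).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

GOOD = "good"
NON_LIMITED = "non_limited"
DEFAULT_RESPONDER_THRESHOLD = 3.0  # % of normal net increase


class CategorizationError(ValueError):
    """Raised when a PBMC course has no usable post-dose values."""


class PairingError(ValueError):
    """Raised when two call sets do not cover the same variants."""


@dataclass(frozen=True)
class PbmcMeasurement:
    """One post-dose PBMC activity determination (% of normal)."""

    timepoint: str
    pct_normal: Optional[float]  # None for ND/NA entries
    dose: str = ""


@dataclass(frozen=True)
class SubjectRecord:
    """One treated subject: cell-based assay values and in-vivo PBMC course."""

    subject_id: int
    study: str
    protein_change: str
    cdna_change: str
    hek_baseline_pct_wt: float
    hek_cmax_pct_wt: float
    hek_responsive_at_cmax: bool
    pbmc_baseline_pct_normal: float
    pbmc_post: tuple[PbmcMeasurement, ...]
    category: str  # GOOD or NON_LIMITED

    @property
    def post_values(self) -> list[float]:
        return [m.pct_normal for m in self.pbmc_post if m.pct_normal is not None]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass
class ConcordanceReport:
    counts: ConfusionCounts
    sensitivity: Optional[float]
    specificity: Optional[float]
    sensitivity_rounded: Optional[float]
    specificity_rounded: Optional[float]
    correlations: dict[str, CorrelationResult] = field(default_factory=dict)
    discordant: list[str] = field(default_factory=list)


def categorize_pbmc_response(
    baseline: float,
    post_values: Sequence[Optional[float]],
    threshold: float = DEFAULT_RESPONDER_THRESHOLD,
) -> str:
    """Categorize an in-vivo PBMC course as good vs non/limited responder.

    "Good" when the maximal net increase over baseline across non-missing
    post-dose values is at least ``threshold`` % of normal (3% by default;
    the boundary itself counts as good).  ND/NA entries are ignored.
    """
    values = [v for v in post_values if v is not None]
    if not values:
        raise CategorizationError("no non-missing post-dose values")
    return GOOD if max(values) - baseline >= threshold else NON_LIMITED


def build_confusion(
    reference_calls: Mapping[str, bool], test_calls: Mapping[str, bool]
) -> ConfusionCounts:
    """Confusion counts of test (HEK) calls against reference calls."""
    if set(reference_calls) != set(test_calls):
        missing = set(reference_calls) ^ set(test_calls)
        raise PairingError(f"call sets cover different variants: {sorted(missing)}")
    tp = fp = tn = fn = 0
    for key, ref in reference_calls.items():
        test = test_calls[key]
        if ref and test:
            tp += 1
        elif ref and not test:
            fn += 1
        elif not ref and test:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity(counts: ConfusionCounts) -> Optional[float]:
    """tp/(tp+fn); None when the reference has no positives."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else None


def specificity(counts: ConfusionCounts) -> Optional[float]:
    """tn/(tn+fp); None when the reference has no negatives."""
    denom = counts.tn + counts.fp
    return counts.tn / denom if denom else None


def pearson_two_tailed(
    x: Sequence[Optional[float]], y: Sequence[Optional[float]]
) -> Optional[CorrelationResult]:
    """Pairwise-complete Pearson correlation with two-tailed p-value.

    Pairs with a missing member are dropped; returns None when fewer than
    three complete pairs remain or either vector has zero variance.
    """
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    pairs = [(a, b) for a, b in zip(x, y) if a is not None and b is not None]
    if len(pairs) < 3:
        return None
    xa = np.array([p[0] for p in pairs], dtype=float)
    ya = np.array([p[1] for p in pairs], dtype=float)
    if np.std(xa) == 0 or np.std(ya) == 0:
        return None
    res = stats.pearsonr(xa, ya)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(pairs))


def log_ec50_molar(ec50_uM: float) -> float:
    """log10 of the EC50 expressed in molar units."""
    if ec50_uM <= 0:
        raise ValueError("ec50_uM must be > 0")
    return float(np.log10(ec50_uM * 1e-6))


# Published lymphoblast comparison over the 75 mutant forms tested in both
# in-vitro assays: 44 responsive and 24 non-responsive in both, 5 responsive
# in lymphoblasts only, 2 responsive in HEK-293 cells only.
def lymphoblast_confusion() -> ConfusionCounts:
    return ConfusionCounts(tp=44, fp=2, tn=24, fn=5)


def _report_from_counts(counts: ConfusionCounts) -> ConcordanceReport:
    sens = sensitivity(counts)
    spec = specificity(counts)
    return ConcordanceReport(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        sensitivity_rounded=None if sens is None else round(sens, 2),
        specificity_rounded=None if spec is None else round(spec, 2),
    )


def lymphoblast_concordance() -> ConcordanceReport:
    """Concordance of HEK-293 calls against the published lymphoblast calls."""
    return _report_from_counts(lymphoblast_confusion())


def hek_vs_pbmc_concordance(
    subjects: Sequence[SubjectRecord],
    threshold: float = DEFAULT_RESPONDER_THRESHOLD,
) -> ConcordanceReport:
    """Concordance of HEK-293 Cmax calls against in-vivo PBMC categories.

    The confusion matrix is built per distinct mutant form (a form is
    reference-positive when its subject(s) show a good PBMC response), while
    the correlations use one pair per subject — subjects sharing a mutant
    form duplicate its cell-based values.
    """
    reference: dict[str, bool] = {}
    test: dict[str, bool] = {}
    for s in subjects:
        cat = categorize_pbmc_response(
            s.pbmc_baseline_pct_normal, [m.pct_normal for m in s.pbmc_post], threshold
        )
        good = cat == GOOD
        reference[s.protein_change] = reference.get(s.protein_change, False) or good
        test[s.protein_change] = s.hek_responsive_at_cmax
    counts = build_confusion(reference, test)
    report = _report_from_counts(counts)
    report.discordant = sorted(
        v for v in reference if reference[v] != test[v]
    )

    hek_baseline = [s.hek_baseline_pct_wt for s in subjects]
    pbmc_baseline = [s.pbmc_baseline_pct_normal for s in subjects]
    hek_cmax = [s.hek_cmax_pct_wt for s in subjects]
    pbmc_max_post = [max(s.post_values) if s.post_values else None for s in subjects]
    baseline_corr = pearson_two_tailed(hek_baseline, pbmc_baseline)
    treated_corr = pearson_two_tailed(hek_cmax, pbmc_max_post)
    if baseline_corr is not None:
        report.correlations["baseline"] = baseline_corr
    if treated_corr is not None:
        report.correlations["treated"] = treated_corr
    return report
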