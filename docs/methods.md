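# Methods

## The assay and its statistical model

The pipeline analyzes a transient-transfection assay in HEK-293 cells that
asks, mutant by mutant, whether the pharmacological chaperone migalastat
(AT1001, 1-deoxygalactonojirimycin) raises total cellular α-galactosidase A
(α-Gal A) activity. Each 96-well experiment carries, at every chaperone
concentration of a 3-fold dilution series (50 nM – 1 mM by default, 0 µM
vehicle included), quadruplicate wells transfected with the mutant cDNA,
with empty vector (endogenous background) and with wild-type cDNA
(transfection control and normalization reference). Enzyme activity is read
as fluorescence of 4-methylumbelliferone (4-MU) released from the synthetic
substrate and calibrated against a 4-MU standard dilution series run on the
same plate.

Per experiment the processing is:

1. **Calibration.** Ordinary least squares of counts on known 4-MU amount
   gives slope (counts/nmol) and intercept (plate blank). At least three
   distinct amounts are required.
2. **Background subtraction.** Replicate-mean raw counts of the vector-only
   wells at concentration *c* are subtracted from the replicate-mean counts
   of mutant (or wild-type) wells at the same *c*, floored at zero.
   Endogenous HEK-293 α-Gal A is itself chaperone-responsive, which is why
   the subtraction is per concentration rather than a single constant.
   Because the plate blank is common to both terms it cancels here, so the
   calibration intercept is deliberately **not** subtracted again when
   counts are converted to activity (avoids double correction).
3. **Units.** Activity = specific counts / slope / protein mass / incubation
   time, in nmol 4-MU/mg protein/hr (1 hr incubation by default).
4. **Limit of quantification.** Any activity strictly below the LOQ —
   300 nmol/mg/hr by default, chosen so that it exceeds 1.645·SD of the
   vector-only activities in at least 90% of experiments (`derive_loq`
   recomputes this empirically as the ceil(0.9 n)-th order statistic of
   1.645·SD per experiment) — is imputed to exactly zero. Values exactly at
   the LOQ are kept. Imputation happens on the absolute scale, before any
   normalization, and is idempotent.
5. **Normalization.** %WT = 100 · activity / (untreated wild-type activity
   of the same experiment). The per-experiment reference absorbs
   between-experiment scale (transfection efficiency, lysate recovery,
   calibration error).

## Concentration–response model

Per experiment, activity vs concentration is fitted with a Hill curve

    A(c) = A0 + (Amax − A0) · c^h / (EC50^h + c^h)

with the **baseline A0 fixed** to the measured 0-concentration mean (after
LOQ imputation) — the baseline is an independently measured quantity, not a
free parameter — and h = 1 by default, because the downstream Cmax
interpolation (below) is the h = 1 form; a free-slope option exists for
stress-testing. With A0 and h fixed the model is linear in Amax, so the fit
profiles Amax out in closed form and minimizes the residual sum of squares
over log10 EC50 alone: an 81-point grid on [log10 cmin − 4, log10 cmax + 4]
followed by bounded Brent refinement (xatol 1e−12). This is deterministic,
independent of starting values, immune to the optimizer stalls that generic
2-parameter nonlinear least squares exhibits on response-free (flat noise)
data, and recovers noiseless parameters to ~1e−10 relative error.

Degenerate and edge cases:

* exactly constant activities → EC50 unidentifiable; reported unconverged
  with a `flat` flag (no exception);
* monotone-decreasing data → converged fit with `top_below_baseline` set;
* **extrapolation rule**: EC50 > 800 µM lies beyond the reliably sampled
  range; the fit is flagged `extrapolated` and the reported maximum
  activity is the observed mean activity at the highest tested
  concentration, never the fitted plateau;
* **range extension**: when the fitted EC50 exceeds one third of the top
  tested concentration the curve has not clearly saturated (top tested
  point < 75% of the plateau rise) and `needs_range_extension` recommends
  repeating with the series extended toward 20 mM. The one-third criterion
  is this package's own operationalization of the saturation judgement; the
  assay protocol states the practice but no threshold.

## Aggregation and classification

Across n ≥ 3 independent experiments (n ≥ 2 tolerated but flagged
non-reportable), mean ± SEM is reported for baseline and maximum activity
on both the absolute and the %WT scale (%WT computed per experiment, then
averaged). The relative increase is the **mean of per-experiment
max/baseline ratios**, not the ratio of the means — the two differ, and the
published per-mutant values are consistent with the former. It is "not
calculable" (NC) whenever a baseline was imputed to zero. Unconverged
experiments are excluded and counted.

Responsiveness is a two-tailed paired t-test (pairing by experiment) at
α = 0.05 with the additional requirement of a positive mean increase, on
one of two bases:

* `max_vs_baseline` — per-experiment maximal activities vs baselines (the
  headline call for the 81-mutant panel);
* `cmax_vs_baseline` — per-experiment activities interpolated at the
  clinically achievable concentration vs baselines (the call used for
  comparison against in-vivo responses).

All-zero mutants give identically zero differences; the statistic is
undefined and the call is non-responsive with a `degenerate` flag. No
multiple-testing correction is applied across mutants, matching the
per-mutant reporting convention of this assay class.

The activity at the clinically achievable plasma concentration
(Cmax = 10 µM, from a single 150 mg oral dose) is

    A(Cmax) = A0 + (Amax − A0) · Cmax / (EC50 + Cmax)

which is bounded by [A0, Amax], monotone in Cmax, and commutes with %WT
normalization.

## Concordance analysis

In-vivo comparator: subjects dosed orally, with PBMC α-Gal A activity
expressed as % of the healthy-volunteer mean (22 nmol/mg/hr). A subject is
a **good responder** when the maximal net increase over the predose
baseline across non-missing post-dose timepoints is ≥ 3% of normal (the
boundary counts as good); ND/NA entries are missing, never zero. Confusion
counts treat the comparator as reference and the cell-based call as test;
sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), reported rounded to two
decimals alongside the raw fractions. The confusion matrix is built per
distinct mutant form; correlations use one pair per subject (22 pairs),
duplicating cell-based values for subjects sharing a mutant form. For the
"after treatment" correlation the PBMC value is the maximal post-dose
%normal — the comparator's exact choice of timepoint is not recorded, and
this choice is flagged as an assumption. The lymphoblast comparison enters
through its published confusion counts (44/24/5/2 over 75 shared mutants);
the underlying per-mutant lymphoblast calls come from a separate dataset
that is not packaged, so its correlations are out of scope.

## Synthetic-data generator

The generator (`pcassay.synthetic`) emulates exactly the structure above.
Expected expressed activity of a mutant is W·[b + (t−b)·c^h/(E^h+c^h)] with
W the absolute wild-type activity; vector wells carry only endogenous
background; wild-type wells carry endogenous + W and are non-responsive to
the chaperone by default (transient overexpression saturates the
folding/trafficking machinery; a switch makes the endogenous background
responsive instead, which is the behaviour of the native enzyme).
`catalytically_active=False` forces zero expressed activity at all
concentrations, emulating mutants that bind the chaperone and accumulate
protein without turnover. Well fluorescence is
blank + gain · nmol released · ε, with ε log-normal with mean exactly 1 and
a chosen CV; a second log-normal factor scales all biological activities of
an experiment. Defaults and their rationale:

| parameter | default | rationale |
| --- | --- | --- |
| wild-type activity W | 33 000 nmol/mg/hr | order of the transfected wild-type reference |
| endogenous background | 2% of W, constant | background is subtracted in the protocol but its magnitude is unpublished; a small constant is assumed |
| well noise CV | 0.10 | together with the experiment-level CV reproduces SEM/mean ratios of ~10–25% typical of the published panel rows |
| between-experiment CV | 0.10 | same calibration target |
| plate blank | 50 counts | small positive constant; cancels in background subtraction |
| gain | 1000 counts/nmol | arbitrary (pipeline is scale-invariant) |
| protein | 0.01 mg/well | typical lysate mass; held constant so noiseless round-trips are exact |
| replicates / experiments | 4 / 3 | the assay's plate design |
| standards | 11 × 3-fold from 3.6 nmol | spans the 1.3 nM–30 µM calibration range at 120 µl |

Determinism: each experiment draws from
`default_rng(SeedSequence((seed, experiment_id)))`; identical inputs give
bitwise-identical serialized tables. The truth sidecar records the
generative parameters **and the realized per-experiment scale factors**, so
recovery tests can separate fitter error from latent scale.

What the generator does *not* emulate: plate-position (edge) effects,
outlier wells, cell-growth or transfection-efficiency drift, substrate
depletion at high activity, or any mechanistic folding/trafficking
kinetics. Passing recovery tests therefore demonstrates correctness of the
estimators under the assay's idealized noise model, not robustness to every
artifact of real plates (the protocol's replication and per-plate controls
are the wet-lab mitigations for those).

## Calibration of the pipeline (measured by the test suite)

* Noiseless simulate → process → fit round trip recovers (baseline, top,
  EC50) to ≤ 1e−6 relative error (measured ~1e−10).
* Under the default noise (well CV 0.10, experiment CV 0.10, 3
  experiments), the across-experiment mean EC50 falls within ±25% of truth
  in ≥ 90% of 200 seeded datasets per profile, for profiles with EC50
  between 1 and 100 µM; the plateau on the %WT scale falls within ±10%
  equally often. The %WT scale is the correct comparison for the plateau:
  the experiment-level scale factor and the noisy per-plate calibration
  move all absolute activities of an experiment coherently and cancel in
  %WT — which is precisely why the assay reports %WT.
* Null mutants (top = baseline) are called responsive in 5.0% of 1000
  seeded runs at α = 0.05 on the max-vs-baseline basis (nominal); the
  Cmax basis is conservative (2.6%).

Problem sizes in the routine test suite (200 seeds per recovery profile,
1000 type-I replicates) are the package's chosen simulation sizes for these
calibrations.

## Known limitations

* The Hill fit reports no per-experiment confidence interval for EC50;
  uncertainty is carried across experiments as SEM, matching the assay's
  reporting convention.
* The extrapolation threshold (800 µM), the range-extension heuristic and
  the LOQ are configuration, not estimates; `derive_loq` can recompute the
  LOQ from vector wells but the published constant is the default.
* The t-test with n = 3 pairs has low power for weak responders and its
  level relies on approximate normality of per-experiment differences.
* Fixture-based analyses inherit the rounding of the printed tables; the
  interpolated 10 µM activities agree with the printed clinical-comparison
  column to ±0.2 %WT for the mutants whose inputs are printed unrounded
  enough to check, and the baseline HEK-vs-PBMC correlation reproduces to
  r = 0.639 within transcription rounding.
* One printed panel row (p.R112H) reports a relative increase despite a
  zero (below-LOQ) baseline, where the stated rule gives NC; the fixture
  preserves the printed value verbatim and the loader does not enforce
  that rule on fixture rows.
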