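# Methods

## The allocation rule

Patients with clinically diagnosed knee OA are allocated from two
baseline variables. BMI is checked first: ≥ 30 kg/m² (inclusive)
allocates to the obesity subgroup regardless of strength. Otherwise
upper-leg muscle strength is compared with the instrument cutoff —
1.2 Nm/kg for isokinetic knee-extension dynamometry, 12 repetitions
for the 30-second chair-stand test — at or above which the patient
enters the high-strength subgroup, below which the low-strength
subgroup. Both strength boundaries are treated as inclusive; the
chair-stand rule is explicitly "12 or higher" and the isokinetic
boundary is handled symmetrically. The rule is deterministic; no soft
assignment is offered.

Strength is measured on the *index knee*: the knee with diagnosed OA;
with bilateral OA, the knee with the highest Kellgren/Lawrence (K/L)
grade; on a grade tie, the knee with the lowest strength. A residual
strength tie is broken deterministically, right before left — the
source material does not specify this case, and the tie-break is this
package's own convention. Missing grades or strengths sort as
worst-case so a knee with known scores is preferred.

## Outcomes and responder analysis

Three outcomes at baseline and 3 months: knee pain (NRS 0–10, or VAS
0–100 harmonized by /10), WOMAC physical function (0–100, higher =
more impaired) and muscle strength (instrument units, never pooled
across instruments). Improvement is signed positive for clinical
betterment (decrease for pain and WOMAC, increase for strength).

The within-group effect size is mean improvement divided by the
baseline *sample* standard deviation (n−1), on complete cases, pooled
across trials within subgroup (the trials' exercise regimes are
comparable and are grouped together). Groups need ≥ 2 complete cases
and non-zero baseline spread; degenerate groups are a hard error.

MIC responder rules: pain improves ≥ 15 % of the individual's own
baseline and/or ≥ 1 point; WOMAC ≥ 12 % of baseline; isokinetic
strength ≥ 30 % of baseline; chair-stand ≥ 2 repetitions. "And/or" is
implemented as logical OR. Percent thresholds are relative to the
individual baseline (the referent is not stated in the source; the
per-patient interpretation is the conventional one). A baseline of
exactly 0 under a pure percent rule is degenerate: such cases are
non-responders and raise a warning. Responder rates are kept unrounded
and integer-rounded only where band rules require it.

## The hypothesis registry and its evaluation conventions

The registry holds exactly 63 hypotheses: 15 proportion-consistency
(3 subgroups × 5 cohorts, ±10 percentage points, compared unrounded
with an inclusive boundary: |deviation| ≤ 10.0 accepts), 30 pairwise
phenotype comparisons, and 18 treatment-response bands.

RQ2 tests are a Pearson χ² without continuity correction for
categorical variables and a pooled-variance (Student) two-sided
t-test for continuous ones — the plain "independent sample t-test",
not Welch. Direction checks compare means (continuous), the
positive-class proportion (male %, surgery %), or a mean ordinal score
(K/L with grades 0/1 merged and scored 1–4; comorbidity counts
top-coded at "3 or more" and scored 0–3). Acceptance requires both
significance at α = 0.05 (no multiplicity correction — deliberately,
as each hypothesis is its own claim) and the expected direction; a
significant difference the wrong way is refuted and flagged.

Two conventions are load-bearing:

* **Dual-instrument OR.** Strength comparisons and strength outcomes
  exist per instrument. A strength hypothesis is accepted when at
  least one instrument satisfies the rule.
* **Shared cell.** Some hypothesis pairs map onto the same
  subgroup-pair × variable comparison (e.g. "low older than high" and
  "high younger than low"). Each unique cell is evaluated once, with
  the expected direction of the hypothesis registered first, and all
  hypotheses on the cell inherit the verdict. One pair — the low- and
  obesity-subgroup claims of being weaker than each other — is
  mutually contradictory; the convention resolves the bookkeeping
  (both inherit one verdict) but the contradiction itself is a defect
  of the hypothesis set, documented, not resolved.

When evaluation runs from printed summary tables, an externally
reported p-value attached to a cell takes precedence over
recomputation, because the original test may have used patient-level
information the summaries cannot reconstruct (the comorbidity
comparison between the low- and high-strength subgroups is such a
case: χ² on the printed category counts gives p ≈ 0.16 where the
source reports 0.02). Directions are always recomputed from the group
summaries. On patient-level data everything is computed from scratch,
and the summary-statistics and raw-vector paths are verified to give
identical p-values.

RQ3 bands derive from hypothesized effects of 0.8 / 0.5 / 0.2 each
± 0.2. The large band is applied as a lower bound only (ES ≥ 0.6) and
the small band as an upper bound only (ES ≤ 0.4): an effect *larger*
than hypothesized cannot refute a "large effect" claim (the source's
own accept/refute pattern — e.g. an ES of 1.05 accepted as large —
requires this reading). The medium band is closed, [0.3, 0.7].
Effect sizes are compared at two-decimal precision. Responder bands
are evaluated on integer-rounded rates: majority strictly > 67, half
inclusive [33, 67], minority strictly < 33. One printed band label
(the low-subgroup strength-MIC "< 67 %") contradicts its own
"majority" hypothesis text and is implemented as the majority band
(> 67 %), treating the printed sign as a typo.

The pooled obesity-subgroup count is carried as the sum of the
per-cohort counts, 577 of 1211 (47.6 % → 48 %); the source prints a
pooled 547 that contradicts its own column sum, its 48 % share and
the gender denominator implied elsewhere, and is treated as a typo.

Aggregation requires exactly 63 verdicts (accepted + refuted +
undefined), reports per-question counts, and rounds the overall
percentage to an integer.

## The synthetic generator

The generator emulates the study conditions so every pipeline stage is
testable end to end: five cohorts with the published sizes
(553/159/100/222/177), instruments (isokinetic in AMS-OA, STABILO,
VIDEX; chair-stand in NEXA, CBT), pain scales (VAS in NEXA and CBT,
exercising the harmonization path), exercise-arm fractions (0, 1, 1,
148/222, 1 — 584 exercise participants in total) and structural
missingness (surgery recorded only in NEXA/CBT, comorbidity only in
AMS-OA/VIDEX). Subgroup mixtures default to the published per-cohort
allocation proportions; subgroup-conditional baselines to the
published subgroup summaries (ages, sex ratios, BMI, strength, pain,
WOMAC, K/L and comorbidity category frequencies, surgery rates); true
standardized improvements δ to the published within-group effect
sizes per subgroup and outcome (strength per instrument).

BMI and strength are drawn from truncated normals confined to the
drawn subgroup's decision region (BMI ≥ 30 for obesity, BMI < 30 with
strength on the matching side of the cutoff otherwise), so label
recovery by the stratifier is exact by construction. Chair-stand
scores are integer-valued (discretized truncated normal); their exact
pmf moments are used wherever a population sd is needed.

Follow-up scores use *mean-calibrated truncated improvement
sampling*: for each subgroup × outcome, individual improvements are
drawn from Normal(c, s²) truncated to the individual's feasible
interval (follow-up must stay on-scale), with the single location c
solved by root-finding so the population mean improvement equals
δ·σ_baseline, where σ_baseline is the analytic sd of the (truncated)
baseline distribution. This keeps the configured δ exactly equal to
the population standardized effect: simple generate-then-clamp
biases the realized effect size by roughly −0.03 at δ ≈ 1 on the
pain scale, which would corrupt parameter-recovery checks. The noise
scale defaults to s = 0.5·σ_baseline — an arbitrary but plausible
individual-response heterogeneity, configurable in the generator
config.

What the generator does *not* emulate: correlations among covariates
within subgroup (ages, BMI, strength, pain and WOMAC are conditionally
independent given the subgroup; the real cohorts surely correlate
them); recruitment differences between cohorts beyond the mixture
weights (within a subgroup, every cohort shares one baseline
distribution); dropout and missing follow-up within exercise arms; and
the joint distribution shaping responder rates — δ pins the *mean*
standardized change, so simulated MIC rates are emergent and need not
match the published ones. Passing tests on synthetic data therefore
demonstrate the correctness of the pipeline's arithmetic and the
internal consistency of rule and generator, not the clinical findings
themselves, which live in the printed-summary fixtures.

## Numerical choices and problem sizes

Deviations, effect sizes and rates are computed unrounded and rounded
only at the comparison points the band rules define (two decimals for
ES, integers for rates) or for display. Ties at band edges resolve by
the stated inclusivities. The calibration root-find uses Brent's
method with the closed-form truncated-normal mean (vectorized over
individuals); infeasible targets (a mean improvement larger than the
scale allows) are a hard error rather than silently attenuated.

Test and reproduction runs use the study-sized dataset (N = 1211);
the parameter-recovery checks use 10 000 patients per cohort
(N = 50 000), where three Monte-Carlo standard errors bound the
effect-size estimates around their configured δ at about ±0.03–0.05
and subgroup means of age/pain/WOMAC at well under a unit.

## Known limitations

* Reproduction-mode RQ2 depends on printed p-values where printed
  counts cannot reproduce the original test (one cell, noted above);
  the package reports which source each verdict used.
* Surgery denominators and per-instrument strength group sizes are
  reconstructed from printed percentages (they are not printed);
  they affect only the recomputation path.
* The contradictory low↔obesity strength hypothesis pair is counted
  per the shared-cell convention; removing either hypothesis would
  change the published totals.
* The generator's independence assumptions make it unsuitable for
  studying covariate-adjustment questions; it is a test harness for
  the decision arithmetic, not an epidemiological model.
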