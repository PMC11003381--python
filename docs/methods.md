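# Methods

This note documents the models, formulas, defaults and design choices
behind `aquatrial`, in the order an analysis runs.

## Diet formulation

A replacement diet substitutes a fraction *f* ∈ [0, 1] of the fishmeal
base inclusion (default 15% of dry matter) with a blend of alternative
protein ingredients mixed at fixed ratio parts.  Substitution is
isonitrogenous: the blend mass is FM base × *f* × *k*, with the
protein-equivalence factor *k* = CP_FM / (ratio-weighted mean blend CP),
so total dietary crude protein is unchanged.  The blend mass is split
across components in proportion to their ratio parts, and the
formulation is closed to exactly 100% dry matter by an inert filler
(microcrystalline cellulose).  Dietary amino-acid composition follows by
linear mixing: each content is Σᵢ inclusionᵢ/100 × contentᵢ.

The bundled gibel carp trial used factors 0.912, 0.960 and 1.008 for its
blends A (1:1:8:2), B (1:1:6:4) and C (1:1:4:6).  These factors are
back-derived from the published inclusion table and shipped as
constants: the three values are mutually inconsistent with any single
ingredient crude-protein vector under linear mixing, so the exact
equivalence rule behind them is not recoverable, and reproducing the
published formulation requires carrying the factors as data.
`equivalence_factor` remains available for deriving factors from
ingredient compositions in new formulations.  Replacement levels printed
as 33% and 67% are treated as exactly 1/3 and 2/3 (the published
fishmeal inclusions 10.00 and 5.00 from base 15.00 imply this).  Oil and
energy balancing across diets is out of scope; per-diet oil inclusions
are accepted as given.

## Amino-acid data model

Compositions are % of dry matter at full floating precision; the
conventional 2-decimal rounding happens only at report time.  The
canonical list has 17 names: 9 essential (lysine, methionine, threonine,
arginine, leucine, isoleucine, valine, phenylalanine, histidine) and 8
nonessential.  Tryptophan is deliberately excluded: it is destroyed by
the acid hydrolysis of routine feed analysis and does not appear in the
9-term quality indices, so the essential set has exactly nine members
everywhere (n = 9 in the geometric means).  The asparagine and glutamic
acid entries are pooled Asx/Glx as analysed; no attempt is made to split
the amide forms.  Readers accept common 3-letter abbreviations via a
fixed alias map.  One known irregularity of the bundled tables is the
cysteine row, which varies across diets far more than other amino acids
(control 2.21 vs A33 1.71% DM); values are ingested as published without
correction.

## Digestibility

ADCs use the inert-marker ratio method with yttrium trioxide:
ADC = 100 × [1 − (feces/diet) × (marker_diet/marker_feces)].  For dry
matter both concentrations are 100, giving
ADC_DM = 100 × (1 − marker_diet/marker_feces).  Negative ADCs are
mathematically possible under assay noise; they are reported unmodified
with a `NegativeAdcWarning`, never clamped, because clamping would bias
group means.  Pooled coefficients (e.g. total essential amino acids)
apply the formula to the *summed* diet and feces concentrations — the
coefficient one would obtain by assaying the pool as a single substance —
rather than averaging the individual ADCs; the two differ whenever
component ADCs differ, and the summed-concentration semantics is the
direct application of the defining formula to the total.

## Protein-quality indices

EAAI = 100 × (∏ᵢ aᵢ/rᵢ)^(1/9) over the nine essential amino acids, with
aᵢ the dietary content and rᵢ the species requirement; DEAAI replaces aᵢ
by the digestible content aᵢ × ADCᵢ/100.  Ratios are **not** capped at 1
(the classic Oser formulation caps them): the bundled trial's published
values are only reproducible uncapped, and uncapped ratios preserve
strict monotonicity in each ADC.  Both indices are evaluated as the
exponential of the mean log-ratio, identical to the product form to
floating precision but safe against overflow/underflow.  Requirement
sets are injectable; the bundled gibel carp set (lysine 3.30 … histidine
0.80% DM, assembled from published dose-response studies) is the
default.  The DEAA ratio profile divides digestible contents by an
arbitrary positive reference pattern (muscle composition or
requirements); with the requirement pattern, 100 × the geometric mean of
the profile equals the DEAAI.

Known reproduction limits: the published B100 EAAI (97.50) and DEAAI
(83.75) do not recompute from the published 2-dp inputs (they give 96.84
and 83.18); they were evidently computed from unrounded laboratory
values.  The discrepancy is documented, not corrected, and the remaining
cells reproduce exactly.

## Performance indices

Standard definitions (see `aquatrial.performance`).  The unit of
analysis is the cage, matching the trial's n = 3 cages per diet; a
`basis` flag on each record documents whether feed intake and weights
are per-fish or cage-total so that FR and FE are computed on a
consistent basis.  Trial duration defaults to 56 days (8 weeks).  The
published FE/PER/PRE values are not recoverable from published group
means alone (per-cage intakes and dead-fish weights were not published);
they are computable on full or synthetic records only.

## Dose-response

The requirement estimator is the continuous one-breakpoint
linear-plateau (broken-line) model y = plateau − slope·max(0, b − x)
with slope ≥ 0.  For fixed b the two linear parameters solve in closed
form, so fitting profiles the breakpoint: a 512-point grid over
[min x, max x] followed by bounded scalar minimisation between the grid
neighbours of the best candidate (xatol 1e-10).  The search is
deterministic — no random restarts — so fits are exactly reproducible
and invariant to point order.  If the profiled optimum clamps the slope
to zero the data have no detectable rising limb; the fit is returned
with the breakpoint at min(x) and flagged `plateau_only`.  R² is
1 − RSS/TSS (0 for constant data).  A quadratic-plateau variant
(y = plateau − c(b − x)², smooth at the join) is provided for
sensitivity analysis, and plain OLS (`fit_linear`) with a t-test on the
slope for the simple linear relationships.  A percentile bootstrap CI
for the breakpoint is available; no further change-point inference is
attempted.  Fits to per-diet means use n = 10 points for the bundled
trial; secondary thresholds (PRE against DEAAI, ADC_CP against ADC_DM)
use the same estimator without any exactness claim.

## Group statistics

One-way ANOVA by the standard between/within decomposition; all-equal
data are flagged degenerate rather than returning 0/0.  Duncan's
multiple range test compares each stretch of p adjacent ordered means
against R_p = q(α_p, p, df_error)·√(MSE/n_h), with Duncan's protection
level α_p = 1 − (1−α)^(p−1), studentized-range quantiles computed
numerically from `scipy.stats.studentized_range` (no lookup tables), and
the harmonic-mean group size n_h (Kramer adjustment; inert for the
balanced designs of practice).  The step-down rule protects
sub-stretches of any homogeneous stretch; maximal homogeneous stretches
share a letter, with "a" on the highest mean, matching the superscript
convention of trial tables.  With two groups the procedure reduces
exactly to the pooled two-sample t-test.  Levene's test
(median-centred) is reported alongside but does not gate the ANOVA, as
no standard remedy is assumed on failure.  With many equal groups at
small n, multiple-letter displays arise at the procedure's nominal
rates; this family behaviour is a documented characteristic of Duncan's
test, not something the package adjusts.

qPCR relative quantities follow multi-reference-gene normalisation:
RQ = E^(−Ct_target) / geomean_refs E^(−Ct_ref), scaled so the calibrator
group's arithmetic mean is 1.  Efficiency defaults to 2.0 per cycle
(none was reported for the bundled trial); per-sample efficiencies are
accepted.

## Synthetic-trial generator

`TrialConfig` defaults encode the study conditions: 10 diets (control +
3 blends × 3 levels), 3 cages × 70 fish, 56 days, initial weight 15.18 g,
feeding rate 3 %BW/d, dietary CP 34.2%, marker 0.10% DM.  The generator
derives its equivalence factors from its own synthetic ingredient
profiles (typical commercial CP values; see `default_ingredients`)
rather than the bundled study factors, since the latter are not
CP-consistent (above).  True per-AA ADCs are a baseline (set so the
control diet's DEAAI sits near 79%) plus a blend-specific shift scaled
by replacement level (−4.5/+4.5/+1.5 points at full replacement for
blends A/B/C), capped at 99.5% because true digestibility cannot reach
100%; the resulting ten true DEAAIs span roughly 76–84% and straddle the
growth breakpoint.  Cage mean SGR is linear-plateau in true DEAAI
(breakpoint 79.5, slope 0.26 per DEAAI unit, plateau 2.46 %/d — the
scale of the bundled trial) plus Normal(0, 0.03) cage noise.  Fecal
concentrations obey marker mass balance exactly before noise, so the
noiseless pipeline recovers every true ADC and DEAAI to numerical
precision; assay noise is multiplicative lognormal (CV 1%), keeping
concentrations positive.  Mortality is binomial (p = 0.965 per fish),
with casualties assumed to die at the geometric mean of initial and
final weight.  Ct values are normal (sd 0.15 cycles) around a
reference-gene baseline with a per-diet shift in true log2 expression
proportional to the ADC shift.  A single seed is expanded via
`SeedSequence.spawn` into one substream per table, so datasets are
bit-reproducible and adding a table type never perturbs existing draws.

What the generator does **not** emulate: individual-fish growth
trajectories and size hierarchies, water-quality effects, leaching or
settling losses during fecal collection (marker recovery is complete by
construction), correlated assay errors across substances, and any
systematic deviation between true and marker-estimated digestibility.
Passing recovery tests therefore demonstrate the correctness and
statistical behaviour of the estimators under the stated model, not the
field accuracy of marker digestibility itself.

## Problem sizes and numerical tolerances

Unit tests exercise noiseless recovery at 1e-9, exact-arithmetic oracles
at 1e-12, and published-table reproduction at the printed 2-dp
precision.  Stochastic properties use seeded, derandomised runs: 200
replicates (n = 30, σ = 0.03) for breakpoint recovery of the estimator,
60 seeds for full-pipeline recovery, 200/100 replicate checks for the
Duncan/t-test equivalence, and 400 simulated ANOVAs for the null
p-uniformity check.  The breakpoint grid (512 candidates) resolves the
profile RSS to far below the refinement tolerance for the data sizes in
scope (tens of points).
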