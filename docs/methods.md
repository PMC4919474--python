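# Methods

This note documents the models, decision rules, generator designs and
numerical choices behind `ldscreen`, in the order the pipeline applies
them.

## Signals and normalization

Each well contributes an LD (lipid-droplet stain) signal and a cell
(cell-stain) signal, both arbitrary nonnegative fluorescence units. Lipid
storage per cell is `ld_signal / cell_signal`; a well with a non-positive
cell signal is unevaluable and becomes a masked titration point rather
than an error. Per plate, solvent (neutral) and positive-control wells are
summarized by their medians (robust to single bad wells; the MAD of the
neutral wells is kept for QC). Percent activity is the affine map

    a = 100 · (x − neutral_median) / (neutral_median − positive_median),

so 0 is the solvent level and −100 the positive-control inhibition level.
This scale is invariant under any positive affine rescaling applied
jointly to a plate's signals, which is what makes plates comparable.
Inhibition is negative, activation positive; downstream direction calls
read the sign. Replicate wells at the same (compound, concentration)
collapse to their median.

The cell channel cannot use the same two-anchor map: the positive control
suppresses lipid storage without killing cells, so its cell-signal median
coincides with the neutral one and the denominator degenerates. Cell
activity is therefore the percent change versus the neutral wells' cell
median; the cytotoxicity cutoff of −50 then literally means "half the
cells lost".

The standard titration is 7 points, 46 µM down by 1:5 steps (floor
46e-6/5^6 ≈ 2.94 nM ≈ the nominal 3 nM). The grid is configurable
(`grid_top`, `grid_ratio`, `grid_points`); 7 is the arithmetic consequence
of the stated range and ratio.

## Dose–response model and fitting

The four-parameter logistic on log10 concentration:

    a(c) = top + (bottom − top) / (1 + (EC50/c)^s)

with `top` the low-concentration asymptote, `bottom` the
high-concentration asymptote, `s > 0` the Hill slope. Fitting is bounded
least squares (`scipy.optimize.least_squares`, trust-region reflective,
analytic Jacobian) in (top, bottom, log10 EC50, log s) space, so the slope
constraint is structural. Bounds: |asymptotes| ≤ 200 (twice the control
window), log10 EC50 within the tested range ±2 decades, slope in
[0.1, 10] — slopes outside that band are not distinguishable from
artifacts on a 1:5 grid, and the upper bound stops the model degenerating
into a step function. Start values are deterministic: `top` from the two
lowest-concentration points, `bottom` from the two highest, the midpoint
by grid search over the tested concentrations at slope 1. No random
restarts; fits are exactly reproducible. Optimizer failure is recorded
(`converged=False`), never raised. An EC50 outside the tested range is
reported with an `extrapolated` flag, not clipped — sub-floor potencies
are real and recoverable from the run-in of the curve.

**Outlier masking.** At most one point per titration may be masked. The
candidate is the largest-|residual| point, but it is judged by its
*deletion* residual: the series is refit without it and the point is
masked only if it deviates from that fit by more than `z_max` (default 3)
times the deletion fit's residual scale. Internally studentized residuals
are useless here — on a 7-point series they are bounded by √3 ≈ 1.73, and
a least-squares 4PL distorts toward a gross outlier, spreading the damage
over all residuals. Deviations under 1 percent-activity unit are never
masked (guards against masking numerically perfect points).

**Concentration dependence.** The extra-sum-of-squares F test compares the
4PL to the mean-only model (df 3 and n−4). Degenerate inputs: both models
perfect → p = 1; 4PL perfect alone → p = 0. Under null (flat) data the
test runs *conservative* (measured type-I ≈ 1% at nominal 5%): the
bounded, monotone 4PL cannot realize its nominal three extra parameters on
noise. Conservatism is the safe direction for a hit-calling gate; the test
suite asserts the one-sided property (empirical type-I ≤ nominal) rather
than exact uniformity, which this statistic does not possess.

## Curve classes and triage

Thresholds (all `ClassThresholds` fields, echoed in every report header):
r2_min 0.9, eff_high 80, eff_low 30, plateau_tol 10, hq_partial_eff 50,
tox_cutoff −50, p_flat_max 0.05, min_point_activity 5 — all in percent
except r2_min and p_flat_max. These are declared defaults of this
pipeline: the qHTS curve-class taxonomy defines the categories, not the
numeric cutoffs.

A fit is *accepted* when it converged, r² ≥ r2_min, the flat-model test
gives p < p_flat_max, and at least two unmasked concentrations respond
beyond min_point_activity. The last gate encodes that activity at a single
concentration carries no concentration dependence; it is needed because a
lone step at the top concentration is always representable by a steep 4PL
with near-zero residual, so fit statistics alone can never demote it.

Efficacy is the response span the fitted curve realizes *within* the
tested range (|fit at c_min − fit at c_max|), not the asymptotic span — a
compound is credited only with what the assay observed.

An asymptote counts as reached when ≥ 2 tested concentrations lie within
plateau_tol of it on the fitted curve. This point-support rule is a strict
refinement of checking the curve ends against the asymptotes (for a
monotone curve it implies that check): under noise, a fit can always bend
a rising tail flat at the final point, but it cannot fake two supporting
points without visible residuals. The refinement was decisive for class
recovery under noise (~87% → 93–96% measured at 10%-of-span noise).

Classification order: accepted + both asymptotes → class 1.1 (efficacy ≥
eff_high) or 1.2 (≥ eff_low); accepted + one asymptote missing → 2.1/2.2
on the same split; not accepted but |activity at c_max| ≥ eff_low → 3;
otherwise 4 (inactive). Direction is the sign of the realized response
(class 3: sign of the top-concentration activity); class 4 is inactive by
definition.

Cytotoxicity: flagged when cell activity drops below tox_cutoff at any
unmasked concentration within the active window (≤ 25× the fitted EC50;
the whole range when no converged fit exists). Quality triage: full curves
(1.1/2.1) are high quality unless cytotoxic; partial curves (1.2/2.2) are
high quality only when additionally efficacy ≥ hq_partial_eff and the
compound belongs to a structural series with ≥ 2 members; class 3 actives
are always low quality; class 4 has no tier. Structural series are
single-linkage components of the Tanimoto graph at threshold 0.7 — triage
only asks "are there ≥ 2 similar actives", which single linkage answers
directly; fingerprints are supplied bitvectors (an RDKit Morgan adapter
exists but the core never requires chemistry I/O).

## Expression stages

*Cutoff.* The expression threshold is the 95th percentile (linear
interpolation, configurable percentile) of all intergenic values pooled
across samples; genes whose maximum never reaches it are dropped.
*Replicate QC.* Pairwise Spearman on log(FPKM+1) over expressed genes; the
replicate with the worst median within-condition rho below 0.95 is removed
iteratively, but a condition never drops below its best 2 replicates
(warned). *DE.* Welch's t on log2(FPKM+1), α = 0.001, log2FC = difference
of condition means on that scale. This is an explicit stand-in: the
original analysis used a dedicated DE engine (CuffDiff), an external tool
with its own dispersion model; the cutoff/QC/clustering/enrichment stages
around it are the reproducible substance, and `de_test` results can be
replaced by any per-gene (log2fc, p) table. Calibration caveat:
Welch–Satterthwaite p-values are visibly non-uniform below ~5 replicates
per group; the calibration tests use 5. *Signatures.* Per-gene Z scores
over condition means (profile shape, not level; zero-variance genes
excluded with a warning), k-means with k = 5, 50 k-means++ restarts under
a fixed seed, labels canonicalized by decreasing cluster size. *Burden.*
Two-sided Wilcoxon signed-rank on paired per-gene |log2FC| vectors
(active vs inactive derivative of the same chemotype); the paired-gene
reading of the burden comparison is documented here because the original
figure legend leaves the paired unit ambiguous. *Enrichment.* Upper-tail
hypergeometric per user-supplied gene set against the expressed universe,
Benjamini–Hochberg across sets. Gene sets are plain id lists; no GO
database is bundled (versioned external resource).

## TAG statistics and epistasis

Classical one-way ANOVA (zero-variance conventions: all identical → p = 1;
identical within groups, distinct means → p → 0) followed by Bonferroni
post-hoc pairwise t tests using the pooled within-group mean square from
all groups (Welch per pair available by option); adjusted p = min(1, m·p).
The epistasis rule on (reference, drug-only, mutant-only, combination):
*independent* when the combination mean is below both singles and both
Bonferroni-adjusted comparisons are significant at α = 0.05;
*same pathway* when neither is significant ("no enhancement",
operationalized exactly as reported adjusted p-values of 1 for the
DGAT1-mutant case); *inconclusive* otherwise. Effect sizes are reported as
percent of the reference mean for descriptive comparison with published
fly results; they are not part of the verdict. The verdict is invariant to
swapping which single perturbation is called drug vs mutant.

## Enzyme assay

Percent inhibition interpolates scintillation counts between the solvent
reference (0%) and the no-enzyme quadruple-mutant background (100%), both
as means of replicate wells: `100·(1 − (c − bg)/(dmso − bg))`. The IC50
fit reuses the 4PL with the low-concentration asymptote constrained to
[−5, 5] percent inhibition (no inhibition at zero inhibitor) and the
high-concentration asymptote free, so partial inhibitors are
representable. A titration is reported as "no inhibition" when the fit
fails or realizes < 10 points of inhibition span in range (the DGAT2-like
flat case).

## Synthetic-data generators

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`; identical seeds are bit-identical.

*Screen.* One plate per grid concentration, each with 16 neutral + 16
positive control wells; raw signals are materialized from a cell baseline
of 5000 units and LD-per-cell levels 2.0 (neutral) / 0.4
(positive-control), so the assembly/normalization path is exercised on
realistic raw numbers. Compound classes are drawn from a screen-like mix
(46% inactive, 18% single-point, the rest split across curve classes,
20% of actives activators). Class exemplar parameters are chosen so each
exemplar is an unambiguous member of its class under the default
thresholds: complete curves have midpoints ≥ 30× inside the range ends
(both plateaus supported by ≥ 2 points), class 2.1 uses midpoint c_max/2
(a 45–55-point unreached-asymptote gap), class 2.2 midpoints sit in
[1.0, 1.5]×c_max (midpoint at/beyond the range while keeping two
responding concentrations), class 3 is an alternating-sign wobble
(±8–15%) with one strong top-concentration point — no monotone curve can
absorb alternating bumps, which is exactly what makes such compounds
unfittable in real screens. Cytotoxic compounds (default 5%) get a
correlated cell-signal sigmoid collapsing to −80% around their own
midpoint. Noise is Gaussian per point; by default `noise_sd` is a percent
of each compound's *realized* response span (assay noise tracks signal;
inactive compounds use the 0..−100 control window), with an absolute mode
available. What the generator does not emulate: plate spatial artifacts
(edge effects), signal-dependent heteroscedasticity within a titration,
correlated plate-to-plate drift, and compound classes outside the
taxonomy. Passing recovery tests therefore demonstrates correctness of
the decision rules and estimators under the stated noise model, not
robustness to structured plate artifacts.

*Expression.* Genic genes get log2-normal baselines (log2 FPKM ~ N(3,1));
planted clusters are upregulated by `effect` log2 units in their own
condition, with per-sample log2 noise. The intergenic background is
|N(0, 0.4)| rescaled so its pooled empirical 95th percentile equals the
requested value *exactly* (default 1.04) — this makes the cutoff stage's
expected output analytic. *TAG.* Normal deviates truncated at zero by
resampling; zero-SD specs give exact means. *Enzyme.* Counts =
background + span·(1 − inhibition), 3 replicate wells per point,
multiplicative Gaussian noise (CV), background 200 / span 4000 counts.

## Problem sizes and determinism

The recovery and calibration analyses use: 500-compound screens (all
classes represented) for class-recovery rates, noiseless and at
10%-of-span noise; 2000 simulated series for ANOVA null calibration; 5000
null genes for DE calibration; 500 seeds per epistasis scenario; 200
seeds for noisy EC50/IC50 bias checks. These sizes put Monte-Carlo error
comfortably below the decision margins they feed. Every stochastic step
takes an explicit seed; the pipeline itself is deterministic given inputs
and config, and reports embed a config hash.

## Known limitations

- Curve classes adjacent in the taxonomy (1.2/2.2, 2.1/1.1) are genuinely
  confusable near threshold boundaries at 10%-of-span noise; measured
  recovery is 93–96%, not 100%, and most confusions move mass between
  quality tiers, not between hit/non-hit.
- The HQ/LQ split inside partial classes depends on structural-series
  support, which requires fingerprints; without them partial curves cannot
  reach high quality.
- `de_test` is not a dispersion-modeling DE engine; treat its calls as a
  well-calibrated screen, not a replacement for count-based models.
- The F-test acceptance gate is conservative by construction (see above);
  borderline shallow responders are more likely to land in class 3 than
  to be falsely accepted.
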