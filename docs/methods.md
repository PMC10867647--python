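# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, the behavior of the synthetic study generator, and
the design decisions taken where more than one reasonable construction
exists. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study model and data layout

A study is a wide feature table — rows are LC-MS features carrying a
metabolite name and an MS2 identification score, columns are samples — plus a
sample sheet giving each sample's subject, group (`C` control, `A` induced
aging, `AE` aging plus exercise), sampling day, ionization mode (`POS`/`NEG`)
and QC flag. The default day grid is {0, 14, 28, 63, 91}: baseline, three
draws during the intervention, and one after recovery. The grid is
configuration, not a constant; every stage reads it from the study's sample
sheet.

Intensities are strictly positive where present. Missing cells are encoded as
empty fields, never zeros, because every downstream stage works on log2
intensities. Positive- and negative-mode features are analyzed separately: a
feature belongs to one channel, and channel splitting keeps only the samples
acquired in that channel and the features observed among them.

## Preprocessing

*MS2 filter.* Features with identification score strictly greater than 0.5
are retained; unscored features are treated as unidentified and dropped. The
threshold is `preprocess.ms2_threshold`.

*Collapse.* When several features map to one metabolite name, the
metabolite's value is the highest feature value. "Highest" is ambiguous
between per-sample and per-feature; the default (`collapse =
"elementwise_max"`) takes the per-sample maximum over the name's features,
ignoring missing cells, which reads the rule literally and is deterministic.
The alternative (`"best_feature"`: the feature with the highest mean
intensity contributes its whole row) is available in configuration.

*QC.* Per-metabolite coefficient of variation over the pooled QC injections
uses the sample (n−1) standard deviation divided by the mean. CV is reported
as evidence of instrument stability; no CV-based removal happens by default
(`preprocess.max_qc_cv` opts in). The PCA runs on log2 intensities with each
metabolite centered; metabolites with any missing value are excluded from the
PCA only.

## Paired differential screen

For each group, the late day (default 63) is compared with baseline (day 0)
within subject. Only subjects observed at both days contribute. The effect is
the mean per-subject log2 ratio — robust to between-subject intensity scale,
unlike the ratio of means — and the p-value is a two-sided paired t-test on
the per-subject log2 differences (Wilcoxon signed-rank via
`differential.test = "wilcoxon"`). The t-test on logs is the standard
metabolomics default for lognormal intensities. Metabolites with fewer than
three complete pairs or zero-variance differences get a missing p-value and
are excluded from classification.

Two strict screens follow: changed = p < 0.05; strongly changed additionally
|log2FC| > 1 (a 2-fold change). No multiple-testing correction gates the
screens — the screen is at raw p, mirroring common practice for this design —
but BH q-values are emitted as an extra column for transparency. Venn-region
counts are exact cardinalities of all 2^k−1 exclusive regions.

## Soft temporal clustering

Each metabolite's trajectory within a group is its per-day median over the
group's samples (arithmetic midpoint for even counts), stored as log2. The
median is taken before any standardization so single outlying samples cannot
define a trajectory; the log scale is where the pipeline's noise model is
additive, so the subsequent row z-scoring (sample sd) preserves trajectory
shape. Zero-variance rows carry no shape and are removed (recorded in the
profile's `dropped_zero_variance`).

Fuzzy c-means is implemented here (it is the method under study, not a
wrapped dependency) with objective J(U,V) = Σᵢ Σₖ u_ik^m ‖xᵢ − vₖ‖² and the
classical alternating updates; distance is Euclidean on the standardized
rows. Initialization draws c distinct data rows with a seeded RNG; iteration
stops when the largest absolute membership change falls below `tol` (1e-6)
or after `max_iter` (300) sweeps. A point coincident with one or more
centroids splits its membership equally among the zero-distance centroids.
The objective is recorded after every membership update and is non-increasing
by construction of the alternating minimization.

*Fuzzifier.* m = 2.0 by default, the customary choice when the original
analysis reports none; `cluster.m = "estimate"` applies the
Schwämmle–Jensen (2010) heuristic, which sets m from the number of profiles N
and the dimensionality D so that uniform noise does not form crisp clusters.

*Cluster count.* Dmin(c) is the minimum pairwise centroid distance, taken as
the median over `repeats` (3) independently seeded runs per candidate c. The
original choice rule is visual inspection of this curve; the automated
stand-in is deterministic: select the largest c whose relative drop
r(c) = (Dmin(c) − Dmin(c+1))/Dmin(c) is at least δ = 0.2. Past the true
cluster count additional centroids split real groups and Dmin collapses, so
the last sharp drop marks the supported count. A flat curve falls back to the
smallest candidate with a warning; `cluster.force_c` overrides the rule.
Because the rule keys on relative drops, noise fluctuations in the flat tail
of the curve can occasionally qualify; the repeats median damps this, and the
manual override remains the escape hatch.

*Core members.* Each metabolite is assigned to its argmax-membership cluster
(ties to the lowest index) and is *core* iff that membership strictly
exceeds 0.7. The heatmap export lists core metabolites grouped by cluster in
descending membership order, with their standardized profiles.

## Pattern templates and cross-group accounting

Five canonical shapes are defined on the study's day grid and z-scored:
rise-then-fall (peak at an interior day, default 28), its mirror
fall-then-rise, monotone up, monotone down, and late rise (flat through the
intervention, rising in recovery). The peak day is `patterns.peak_day`.
Centroids are assigned to the best Pearson-correlated template (ties to the
lowest pattern id); correlation makes the assignment invariant to affine
rescaling of the centroid. Zero-variance centroids are an error.

For two groups, core metabolites present in both are compared: a metabolite
*changed pattern* iff its cluster's template differs between the groups. The
report also carries both membership values and their delta, since "the score
of clusters changed" can mean either the cluster index or the membership
value — both columns are emitted.

## Mixed-model trend classes

Per metabolite and group, log2 intensity is modeled with a subject random
intercept (repeated measures) and polynomial fixed effects of scaled time
t = day/max(day) ∈ [0, 1], centered — scaling and centering keep the
quadratic term numerically well-conditioned:

    M0: y ~ 1           + (1 | subject)
    M1: y ~ 1 + t       + (1 | subject)
    M2: y ~ 1 + t + t²  + (1 | subject)

Fits are maximum likelihood (not REML) so likelihood-ratio tests between the
nested fixed-effect structures are valid: p_lin = LRT(M1, M0), p_quad =
LRT(M2, M1), each χ²(1). Fitting goes through statsmodels MixedLM with an
optimizer fallback chain (lbfgs → bfgs → powell → nm), because the default
optimizer occasionally fails on the intercept-only model with a boundary
variance estimate; all optimizers agree on the log-likelihood where they
converge. Unbalanced data — the day-63 attrition — simply shortens each
metabolite's likelihood; nothing is imputed. Metabolites observed on fewer
than two distinct days are flagged unconverged and classified `none`.

Classification reads "model order" as polynomial order: `model2_up/down`
when p_quad < α (direction = sign of the quadratic coefficient: up = convex /
late rise, down = concave / mid-course peak), else `model1_up/down` when
p_lin < α (sign of the slope), else `none`. α defaults to 0.05. The
quadratic-direction convention is an interpretation; `lmm.model2_direction =
"net_change"` would use the fitted end-minus-start difference instead, and
`lmm.select = "aic"` replaces the two-stage LRT order choice with AIC
(still gated on the winner's LRT p). A pure quadratic trajectory on this
asymmetric day grid has a nonzero linear component, so planted quadratics
often show significant p_lin as well; the quadratic-first rule keeps them in
model2.

*Concordance.* A metabolite is selected when its direction (up/down) agrees
between C and AE and is opposite in A; `none` has no direction and never
matches. Directions, not full four-way labels, are compared by default —
exercise restoring the control *direction* is the scientific question —
with `lmm.concordance = "class"` available for the stricter reading.

## Enrichment

One-sided hypergeometric over-representation: for a pathway holding K of the
N universe metabolites, with n selected and k of them in the pathway,
p = P[X ≥ k], X ~ Hypergeometric(N, K, n). The universe is the set of
metabolites that survived preprocessing (intersected with the annotation),
not all annotated compounds — the selection could only ever have drawn from
what was measured. Pathways overlapping fewer than `enrich.min_k` (1)
selected metabolites are omitted. BH q-values are reported but ranking is by
raw p. Compound-class composition tallies the selected set by the
annotation's class map, with `unclassified` as fallback. The packaged toy
annotation (12 pathways over the generator's metabolite names) exists so
tests and examples need no external service.

## The synthetic study generator

The generator emulates the structure the analysis assumes, with ground truth
for every planted effect. Log2 intensity of metabolite i in sample
(group g, subject s, day d):

    y = baseline_i + effect_size · shape_ig(d) + b_is + e,
    b_is ~ N(0, subject_sd²),  e ~ N(0, resid_sd²),

intensity = 2^y (lognormal noise — no noise model is stated for the original
data, and lognormal matches the log-scale analysis). Shapes come from the
same template library the pattern module analyzes, so generator and analyzer
share one shape definition. Defaults: 3 groups × 15 subjects × 5 days,
effect_size 1.0 (the standardized trajectory amplitude), subject_sd 0.3,
resid_sd 0.3, baseline log2 ~ N(20, 2²).

Planted metabolite kinds: *archetype* (one template shape in every group;
cluster-recovery truth; 12 per template by default), *concordant* (monotone
up in C and AE, down in A, alternating with the mirrored planting;
concordance truth; 15 by default), and *null* (no time effect; calibration
truth; 25 by default). The ~60/40 POS/NEG split and the metabolite count
(100) keep the default study representative while letting the full pipeline
and its two end-to-end reruns finish in a few minutes; the tiny fixture
(≤ 30 metabolites, 6 subjects) backs unit tests, and the null fixture
(150 nulls, 10 subjects) backs type-I checks.

Realism knobs: every metabolite gets `n_features_per_metabolite` (2)
duplicate features — the primary always scores above the MS2 cutoff, the
rest draw scores straddling it, sit slightly below the primary in intensity
(offset mean −0.2), and add per-cell jitter (sd 0.05) — so the filter and the
collapse are genuinely exercised. QC injections scatter around each
metabolite's grand mean with sd 0.1. Day-63 attrition removes whole blood
draws (both channels) per subject with probability 0.10, reflecting reported
long-study attrition without a stated rate.

What the generator does **not** emulate: chromatographic drift, batch
effects, ion suppression, correlated metabolite blocks, heavy-tailed or
intensity-dependent noise, and missingness other than day-63 attrition.
Passing recovery tests therefore demonstrates the pipeline's correctness
under its own model assumptions, not robustness to instrument artifacts.

## Numerical conventions

- Row standardization and CV use the sample (n−1) standard deviation.
- All screens are strict inequalities (p < α, membership > 0.7, score > 0.5,
  |log2FC| > 1); boundary values fail.
- Argmax ties (cluster assignment, pattern assignment) break to the lowest
  index.
- Serialized floats carry 6 significant digits; readers should compare
  round-tripped values at ~1e-6 relative tolerance.
- All randomness flows from explicit seeds through `numpy.random.default_rng`;
  derived seeds come from `SeedSequence` so per-group/per-repeat streams are
  independent and reproducible.

## Known limitations

- The Dmin elbow rule can be fooled by relative drops between already-tiny
  values in the curve's flat tail (see above); inspect `dmin_curve.tsv` when
  the selected c looks off, and use `cluster.force_c` to pin it.
- The hypergeometric test treats metabolites as exchangeable; correlated
  metabolites (isomers, pathway neighbors) inflate its optimism.
- MixedLM likelihood-ratio p-values are asymptotic; at very small subject
  counts the type-I rate drifts above nominal (the test suite checks the
  10-subject design stays within 3–7% at α = 0.05).
- Trend classes consider polynomial order ≤ 2 only — no splines, no random
  slopes.
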