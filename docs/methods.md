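# Methods

This note documents the statistical model behind `tractwise`, the
choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## The analysis model

A tract profile is FA sampled at N equidistant nodes (default 100)
along a tract's core. For a planned comparison — a set of tracts, one
behavioral measure, a set of control covariates, one cohort — the
node-wise statistic is the partial Pearson correlation computed by the
residual method: both the measure and the node's FA are regressed on an
intercept plus the controls, and the residuals are correlated. The
significance reference is t = r√(df/(1−r²)) with df = n − 2 − k
(k = number of controls), two-tailed. The residual method and the
inverse-correlation-matrix formula agree to ~1e-12; the df convention
is the standard one for residual-based partial correlation.

Listwise deletion is applied once per comparison, not per node, so the
subject set is identical at every node. This keeps cluster extents
comparable along the tract; the alternative (per-node deletion) would
let n vary across nodes and make cluster sizes incoherent.

### Cluster inference

Clusters are maximal runs of adjacent nodes with p < α_node (default
0.05, two-tailed) and a consistent correlation sign; runs of mixed sign
are split at the sign changes, since a physiologically interpretable
cluster has one direction of association.

FWE control uses the max-statistic permutation method. Per permutation,
the measure is shuffled across subjects — one shuffle shared by all
tracts in the family, so the recorded maximum honestly reflects the
family-wise search — FA and covariates stay fixed, the node-wise maps
are recomputed, and the maximum sign-consistent cluster size over the
whole family is recorded (0 if nothing is suprathreshold). The critical
size is the smallest observed null maximum whose exceedance proportion
(ties included) is ≤ α_FWE; if no null value qualifies, one more than
the largest null maximum. This is deliberately conservative at ties and
uses no percentile interpolation. When every permutation yields 0, the
critical size is therefore 1.

Two permutation schemes are exposed. The default shuffles the raw
measure labels, which matches the common along-tract multiple-comparison
implementations; `freedman_lane` permutes the residuals of the measure
on the covariates and adds back the fitted values, preserving the
measure-covariate relation under the null. Both are available in the
study config; results on the synthetic cohorts are very similar because
the generator's covariate-score couplings are modest.

Permutation i draws its shuffle from `default_rng([master_seed, i])`, an
independent substream per permutation, so the null is reproducible and
independent of execution order.

The lenient exploratory rule — ≥ 9 adjacent uncorrected-significant
nodes at 100-node resolution, ≥ 3 at 30-node — is a fixed map from
resolution to minimum run length and is reported alongside the FWE
decision, never instead of it.

### Cohort-comparison statistics

The partially overlapping samples t-tests implement the Derrick, Russ,
Toher & White (2017) statistics. For the Welch-type df we use the
partially-interpolated form ν₂ = (n_c−1) + (γ−n_c+1)(n_a+n_b)/(n_a+n_b+2n_c)
with γ the Welch–Satterthwaite df, which collapses to γ at n_c = 0 and
to n_c − 1 when fully paired. Note the exact-collapse algebra: at
n_c = 0 both variants equal the corresponding independent t-test
exactly; when fully paired the Welch-type denominator equals the
paired-t denominator for any data, while the equal-variance variant
matches the paired t exactly only when the two sample variances are
equal (its pooling assumption). The paired correlation r is the Pearson
correlation of the n_c paired observations only, and requires n_c ≥ 2.

The rank-sum test uses mid-ranks, the tie-corrected normal variance
Var = (n₁n₂/12)((N+1) − Σ(t³−t)/(N(N−1))) and a 0.5 continuity
correction. With ordinal 5-level data and cohort sizes in the low
hundreds this reproduces the reference asymptotic implementation
(scipy's Mann-Whitney with tie correction and continuity) to machine
precision.

### Profile quantification

Streamlines are resampled to N points at equal arc length (linear
interpolation along the polyline; endpoints preserved). The tract core
is the per-node sample mean and covariance of positions, with ε·I
(ε = 1e-6 mm²) added so degenerate bundles remain invertible. The
weighted profile assigns each streamline, at each node, the
multivariate-normal density of its position under the core — a Gaussian
function of Mahalanobis distance — normalized to sum to one, and takes
the weighted FA sum. This density weighting is one faithful reading of
AFQ-style distance weighting; hard outlier exclusion is a documented
alternative not implemented. The resulting profile is a convex
combination of streamline FA values and is invariant under rigid-body
motion of all coordinates.

The 100-to-30-node reduction used for confirmatory analyses is linear
interpolation at 30 equally spaced arc positions: "equally spaced
nodes" describes positions, and interpolation (unlike block averaging)
preserves the endpoints exactly and is idempotent at fixed resolution.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes, at the
motivating study's scale: two age cohorts (81 and 164 subjects,
default) with 45 subjects observed in both; scores on the behavioral
battery's reporting scales (scaled scores ~11±2–3 for the phonological
and semantic measures, standard scores ~107–122±12–17 for nonverbal IQ,
core language and word reading, per-cohort means mirroring the
published cohort summaries), rounded to integers; ages uniform in each
cohort's range; maternal education drawn from the published level
frequencies with ~4% missing.

Scores share a one-factor correlation structure: a per-subject common
factor (correlation `measure_correlation`, default 0.3, between any two
measures) plus a per-(subject, measure) stable factor that raises the
same-measure cross-cohort correlation of paired subjects to
`pairing_correlation` (default 0.6). The published work reports no raw-
score generative detail, so these are field-plausible choices, fixed
once.

FA profiles are a smooth per-tract mean shape (within 0.3–0.6) plus a
per-subject scalar offset (SD 0.03 FA units) plus stationary
Gaussian-smoothed white noise along nodes (per-node SD 0.04). The
smoothing kernel has unit L2 norm, so the per-node noise SD is exact,
and its autocorrelation is known in closed form. The correlation length
(kernel SD) defaults to 3 nodes, chosen so that the max-cluster-size
permutation null at 100-node resolution yields FWE critical sizes of
roughly 14–17 nodes — the regime the along-tract FWE procedure operates
in on real AFQ profiles, where stringent thresholds around 15 adjacent
nodes are typical. Smoother profiles inflate null cluster sizes and the
critical size with them.

**Effect embedding is analytic, not tuned.** An `EffectSpec` adds
b·z to FA at every node of its window, where z is the standardized
residual of the (already rounded) score on the effect's controls and
b = ρ/√(1−ρ²)·σ_win, with σ_win² the exact variance of the window-mean
FA noise computed from the kernel autocorrelation:
σ_win² = subject_sd² + node_noise_sd²·mean_{j,k∈W} ρ(|j−k|). The
population partial correlation between the score and window-mean FA,
given the same controls, is then exactly ρ; at n = 2000 the realized
value is within ~0.02 of target (clipping FA to (0.01, 0.99) perturbs
it negligibly at the default noise levels).

What the generator does **not** emulate: real DWI acquisition noise,
tensor-fit bias, tractography failures, spatially varying node-to-node
covariance, hemispheric or tract-shape realism, score floor/ceiling
effects, or any relationship between FA and age beyond independence.
Passing tests therefore establish the correctness and calibration of
the *statistical procedure* under its own assumptions, not claims about
any real dataset; published node ranges cannot be (and are not)
reproduced.

## Study pipeline

Inclusion filtering applies thresholds in a fixed precedence order —
nonverbal IQ ≥ 70, core language ≥ 80 (both inclusive), mainstream-
English requirement, the ±3-SD within-cohort outlier rule on the three
ability scores, right-handedness, no reported diagnosis — logging the
first failing rule per subject. The outlier rule is evaluated on the
survivors of the earlier rules so its means and SDs are not distorted
by already-excluded subjects. Retained + excluded counts always equal
the input count exactly.

`run_study` executes demographics (rank-sum on maternal education;
partially overlapping t-tests on all score columns, Welch-type for the
phonology score whose cohort SDs differ notably, equal-variance
otherwise) and then every configured comparison family. An
`overlap_only` flag restricts both cohorts to subject keys present in
both, for sensitivity reanalyses of the paired subsample. Each family
gets its own seed substream derived from the master seed, so adding or
reordering families does not perturb other families' results.

Whether dorsal tracts form one permutation family or two is a genuine
ambiguity in along-tract studies; the comparison config makes the
family explicit (the tracts listed in one `ComparisonSpec` are one
family), so either convention is expressible.

## Problem sizes and numerical choices

The validation suite uses cohorts of 164 analysis subjects, two tracts
of 100 nodes, 200–500 permutations, 200 null replicates for
false-positive calibration and 50 replicates for effect recovery —
sizes at which the binomial error of the measured rates is well inside
the asserted bands while the whole suite stays fast. Degenerate inputs
(constant FA, a covariate duplicating the measure, all-zero
eigenvalues, single paired observation) raise typed errors rather than
NaNs; numerically-constant residual vectors are detected by a
scale-relative threshold. Node indices are 1-based in all files,
reports and cluster coordinates, 0-based internally.

## Known limitations

* The Welch-type df form cannot be cross-checked against published
  values computed from raw data; with the published summary statistics
  it lands within 0.1 df of the published Elision row.
* The permutation null assumes exchangeability of subjects under the
  null; covariate-driven heteroscedasticity would call for the
  Freedman–Lane scheme, which is exposed but not the default.
* The max statistic is taken over the tracts within one comparison
  family, not across families; family-level error is controlled per
  family, as in the pre-registered-comparison design it mirrors.
* The generator's effect is additive and uniform across its window;
  tapered or node-varying effects would dilute edge nodes and lower
  recovery rates relative to the rates reported here.
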