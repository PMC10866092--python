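# Methods

## Scope and data model

The package analyzes regional immediate-early-gene (FOS) expression in
a 2 × 2 × 3 design: genotype (AA, GG), sex (M, F), and treatment
(saline, acute, chronic opioid). The regional atlas covers 24 regions
of interest grouped into eight anatomical meso-structures (cortex 7,
striatum 2, pallidum 4, amygdala 2, thalamus 3, midbrain 4,
hippocampus 1, hypothalamus 1). Dynamics are computed on a 23-region
subset; which region is excluded is configurable (default: SNr, the
last-listed midbrain region) because the choice is not dictated by the
analysis itself, only by which regions a structural connectome covers.

## Synthetic data generator

`synthio` emulates the statistical structure the analysis assumes, not
any particular animal dataset:

- **FOS densities** follow a multiplicative log-normal model
  `density = baseline_i · effect_{g,i} · exp(s_g f_{m(i),a} + eps)`
  with one standard-normal latent factor per animal and meso-structure,
  group loading `s_g`, and residual SD `noise_sd` on the log scale.
  This is the simplest model that yields strictly positive densities
  and controllable modular covariance — the two properties the
  percent-change and correlation steps rely on.
- Defaults: 7 animals per cell (the study design used 6–8; 7 is the
  configurable compromise), baselines drawn once uniformly in
  [50, 400] cells/mm² from the generator seed, acute fold change 3.0
  in every group, chronic fold change group-dependent (1.8–3.5, largest
  in GG females so the dependent state is displaced furthest there),
  module strength 1.0, noise SD 0.5, outlier probability 0.02.
- **Outliers** are multiplicative (×U[5, 10]) so the robust filter has
  a well-defined target.
- **Connectomes** are directed Bernoulli(density) graphs with
  log-normal weights; no attempt is made to mimic real anatomical
  connectivity values. **Receptor maps** are log-normal nonnegative
  vectors, optionally with the mu density enriched on a designated
  high-influence region subset.

What the generator does *not* emulate: imaging noise structure,
spatial autocorrelation beyond the meso-structure blocks, litter or
batch effects, and realistic connectome topology. Passing tests
therefore demonstrate correctness of the computational pipeline and
its statistical behavior under the stated generative assumptions, not
biological conclusions about real animals.

## Preprocessing

Per-animal density is the mean of count/area over usable (non-damaged)
sections; an animal-region with no usable section becomes missing and
is never imputed. Outlier screening is a one-sample analogue of the
ROUT procedure: robust center = median, robust scale = 1.4826 × MAD, a
t-like statistic per point with a two-sided p-value on n−1 degrees of
freedom, and Benjamini–Hochberg at rate Q = 0.05. The original ROUT is
formulated around robust regression, which degenerates for a
single-group location problem; this re-specification keeps its two
essential ingredients (robust fit, FDR-controlled residual testing) and
is documented as an approximation — the original software's exact
critical values are not reproduced. With fewer than three values the
input passes through unchanged; when the scale collapses to zero, only
points strictly off the median are flagged, so all-equal groups are
never touched.

Percent change is `100 (x − b̄)/b̄` with the baseline b̄ the mean saline
density per region within the same genotype × sex stratum. The study
text does not state whether baselines pool across strata; stratified is
the default because group-specific changes are displayed per stratum,
and a pooled mode is available by flag. Bootstrap brain states resample
animals with replacement at the original n (configurable) and take
region-wise means; a resample that misses every observation of a
region falls back to the full-group mean for that region so state
vectors stay finite.

## Networks and graph metrics

Pearson correlations are computed across animals with pairwise deletion
(minimum three complete pairs; constant vectors yield missing entries
with a warning). Edges require R > threshold (default 0, exactly the
positive-correlation rule; an optional significance filter exists but
is off by default). Edge length is −ln R with natural logarithm — the
base only rescales all distances uniformly, so shortest-path structure
is invariant — and perfect edges (R = 1) are clamped to 1e−12 so path
algorithms stay defined.

Sigma is computed on the binarized graph (the standard definition);
its random ensemble is 100 degree-preserving rewirings, each applying
10·|E| attempted double-edge swaps. Attempt counting (rather than
requiring successful swaps) keeps rigid graphs such as complete graphs
well-defined: they pass through unchanged and sigma is exactly 1. An
Erdős–Rényi null matched on N and |E| is available by flag. Means over
path lengths use reachable pairs only, with the unreachable count
reported. Group closeness excludes outside nodes unreachable from the
group (a harmonic variant is available by flag). Communicability
betweenness follows the standard matrix-exponential normalization
((N−1)² − (N−1)); all metrics are verified against exhaustive
enumeration oracles on small graphs.

One empirical caveat established by the test suite: single-network
sigma estimates from correlation networks are noisy even at large n,
because highly correlated within-module regions make between-module
edges appear and disappear in blocks. Comparisons of sigma between
groups are therefore most reliable when averaged over independent
network realizations (split-half samples or separate conditions), and
the group-recovery test does exactly that.

## Control energetics

The continuous-time LTI model uses A\* = A/(λ_max + 1) − I with horizon
T = 1. Neither the normalization nor T is dictated by the analysis
being reproduced; both follow the dominant convention in the
network-control literature, and T only rescales energies
monotonically. States are raw percent-change vectors (not divided by
100), so energies are comparable only within this unit convention.

The Gramian is integrated by Simpson's rule on a uniform grid
(default 1001 nodes; doubling the grid changes energies by under
0.01%), with matrix exponentials via scaling-and-squaring propagated
along the grid by a single-step recurrence. Because B is diagonal, the
Gramian decomposes as W = Σ_j w_j² W_j over per-column Gramians, so
suppression, receptor weighting, and weight-scaling are exact algebra
on precomputed pieces — this also makes the 1/c² weight-scaling law
hold to machine precision. Energies use the pseudo-inverse with
relative cutoff 1e−10; the reachability residual ‖WW⁺v − v‖/‖v‖ is
reported and transitions with residual above 1e−6 are flagged
unreachable. Suppression drops the control column (weight 0); a small
positive floor is configurable for near-singular systems. Random-subset
nulls for target-set suppression draw equally sized subsets from the
regions outside the target set, and the one-sample t statistic is
(target effect − null mean)/(null SD/√n), positive when the target set
is more influential than chance. The connectome orientation (rows =
targets) is fixed in configuration; transposing is a flag since source
data conventions vary.

## Statistics

Per-region three-way ANOVA uses type-III sums of squares (the designs
are unbalanced after outlier removal) with sum-to-zero contrasts;
post hocs are Tukey HSD or Šídák-adjusted pairwise t tests by
configuration. Degenerate effects (zero sum of squares, e.g. constant
data) are reported as F = 0, p = 1 rather than 0/0. The Friedman test
uses the classical rank statistic with Dunn's z pairwise comparisons,
Bonferroni-adjusted (the adjustment is a package choice; the source
analyses do not state one). Wilcoxon matched-pairs uses the exact small-
sample null when there are no ties. The sigma-change vs energy
regression z-scores both variables over the pooled sample and fits OLS,
reporting slope with 95% CI, R², and the overall F test.

## Pipeline sizes and determinism

A full run computes, per group: the correlation network, sigma with a
100-rewiring ensemble, a bootstrap sigma distribution (default 20
networks per group), 200 × 200 bootstrapped pairwise transition
energies, per-region suppression, target-set suppression against 100
random subsets, mu/delta/kappa receptor-weighted energies, persistence
energies, and 8 paired sigma/energy bootstrap replicates pooled into
the regression (32 points). These sizes are package defaults chosen to
keep a desk run in minutes; all are configurable. One global seed
spawns independent per-stage substreams (SeedSequence spawn keys), so
any stage can be rerun in isolation and identical configurations give
identical manifest hashes.

## Known limitations

- The ROUT analogue approximates, not replicates, the commercial
  implementation.
- Sigma on dense correlation graphs (density ≳ 0.6) compresses toward
  1 regardless of modular structure; interpret group differences in
  sigma jointly with density.
- Energies depend on the (unstated-by-convention) normalization and
  horizon; only ratios and orderings within one convention are
  meaningful.
- The synthetic connectome is statistically, not anatomically,
  realistic; absolute energy magnitudes are not comparable to analyses
  on real tract-tracing connectomes.
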