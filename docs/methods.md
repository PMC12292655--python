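# Methods

This note documents the statistical model behind `dndnet`, the tunable
parameters, the synthetic-study generator, and the numerical and design
choices a user should know before trusting (or extending) the results.

## Pipeline model and assumptions

**Preprocessing.** Outlier handling uses two detectors in PCA space
computed on the per-feature z-scored matrix (SVD; components ordered by
variance, with the sign convention that each component's
largest-magnitude loading is positive, so repeated runs agree):

- *Stage ellipses*: per stage, the (PC1, PC2) scores are summarized by
  their mean and covariance; a sample is flagged when its squared
  Mahalanobis distance to its own stage's centroid exceeds the
  chi-square(2) quantile at the chosen confidence (default 0.95). This
  assumes approximate bivariate normality of the leading scores within
  a stage.
- *Pooled Mahalanobis*: distances to the pooled mean in k-dimensional
  PC space (k defaults to the number of components explaining 90% of
  variance, capped at 10) against the chi-square(k) quantile.

Because repeated biopsies from one subject are statistically coupled,
the exclusion unit is the subject: any subject owning a flagged sample
is removed entirely. The flag-combination policy (union by default;
intersection or single-detector alternatives) is configurable because
reasonable cohorts differ in how aggressive exclusion should be.

Cohort separation along the stage axis is quantified by PERMANOVA on
Euclidean distances: pseudo-F from the distance-matrix sums of squares,
p from label permutations. When the number of distinct labelings is
small enough the null is enumerated exhaustively (p = count/total,
observed labeling included); otherwise random shuffles with the add-one
estimator p = (1 + #{F* ≥ F}) / (1 + n_perm), which cannot return 0.

The three-part feature filter keeps the union of (1) features whose
Pearson correlation with any phenotype column is significant (t-test on
r, default p < 0.05, optional Benjamini–Hochberg), (2) an external
whitelist (e.g. tissue-specific databases), and (3) features with a
significant one-way ANOVA across stages. Union rather than intersection:
the three parts capture complementary notions of relevance, and an
intersection would discard stage-responsive features merely absent from
curated lists.

**Reference network and SSNs.** Only background-network edges are ever
evaluated — correlation is computed on prior-knowledge edges, not on all
feature pairs — and an edge enters the retained network when its
reference-cohort correlation is significant at `edge_alpha` (default
0.05, t-transform of r with n−2 df). The SSN perturbation statistic for
sample d is sPCC = PCC over reference+d minus PCC over reference, tested
with z = sPCC / ((1 − PCC²)/(n−1)) and a two-sided normal p. Reference
samples are scored leave-self-out (their sPCC is PCC over the full
cohort minus PCC with themselves excluded), which avoids
self-perturbation bias while keeping the retained topology fixed from
the full reference.

*Calibration caveat.* The z-statistic's exact asymptotic null is not
normal: writing the added sample's standardized coordinates as (a, b),
the normalized perturbation converges to a product of two independent
standard normals, which has unit variance but excess kurtosis ≈ 5.5.
A nominal two-sided 5% test therefore rejects about 6–7% of
reference-distributed samples regardless of reference size. The
acceptance suite measures this; users needing exact size control should
tighten `ssn_alpha` accordingly (e.g. alpha 0.035 yields ≈5% empirical
size) or treat SSN significance flags as descriptive.

**Scoring.** The local module of center x is x plus its downstream
out-neighbors in the *retained reference network*; module topology is
therefore sample-independent, and the per-sample SSN only supplies edge
statistics. Is(x) = sED_in · sPCC_in / sPCC_out with absolute values
throughout (deviation and perturbation magnitudes, keeping Is ≥ 0). A
center with no retained downstream edge scores 0 — by construction it
cannot drive anything. Features are never treated differently by kind:
miRNAs are scored exactly like mRNAs, with their directionality coming
from the miRNA→target edges of the background network.

*Boundary floor.* When a module has no first-to-second-order boundary
edge the denominator sPCC_out is undefined. The scoring primitives take
an explicit floor argument (1e-6 by default, which deliberately treats
a missing boundary as maximal outside-decorrelation); the pipeline
default instead substitutes the **median |sPCC| of the sample's SSN**.
The tiny fixed floor is appropriate when a single feature's trajectory
is examined in isolation, but for cross-feature ranking it inflates
every boundary-less module by ~10⁶ and buries genuine modules, so the
adaptive floor — "no boundary ≈ null-level decorrelation" — is what
candidate selection and sample scores use.

**Aggregation and selection.** The per-sample DND score is the mean of
Is over all scored features (mRNA and miRNA pooled; a top-k variant is
available). Stage means are arithmetic means of the per-sample scores
within a stage. Candidates must (a) increase strictly along the declared
stage order and (b) land in the top `top_fraction` (default 0.10) of
final-stage means; both parts are configurable since the tradeoff
between sensitivity and list size is study-specific. Trend diagnostics:
paired t-tests on subject-matched stage means for adjacent stages; the
uptrend count over subjects complete in all stages; and an adjusted ICC
— the one-way between-subject variance fraction of the residuals after
removing stage means (unequal group sizes handled with the k₀
correction). Low adjusted ICC means stage, not subject identity, drives
the score. The stage-mean-removal step gives the null estimator a small
positive bias (≈ +0.02 at 20 subjects × 3 stages), measured in the test
suite.

**Network control.** The candidate-induced subgraph of the background
network is decomposed into strongly connected components; each
nontrivial component (≤ 20 nodes, configurable) is solved exactly by
subset search in increasing size with a lexicographic tie-break, which
makes results reproducible and the reported set the lexicographically
smallest optimum. Larger components fall back to a heuristic:
iterative source/sink elimination, self-loop forcing, greedy removal of
the node maximizing in-degree × out-degree, and a final
minimality-pruning pass so no proper subset of the returned set is
itself an FVS. Drivers are FVS nodes sorted by background out-degree
(descending, ties by id): a regulator with many targets is the more
plausible master switch.

## Synthetic-study generator

The generator produces what the pipeline needs to be tested end-to-end:
an ordered three-stage cohort with per-subject repeated measures, a
directed background network (TF-like mRNA hubs with geometric
out-degrees; miRNA nodes regulating only mRNAs), and a planted driver
module — a hub center wired to 8 targets, each target to 3 downstream
boundary genes, 3 targets looping back to the center (so every feedback
loop passes through the center, making it the unique minimum FVS), and
2 miRNAs repressing module genes. The center is given the largest
out-degree in the network by construction.

Expression follows a latent-factor model, chosen over a dynamical
simulation because the DNB conditions are statements about second
moments that a factor model realizes directly:

- Each subject s has a non-negative severity trait u_s ~ |N(0,1)|;
  sample-level severity is z = (u_s + j·ε)/√(1+j²) with within-subject
  jitter j = 0.3. Severity is modeled as non-negative because subjects
  progress by different amounts but none in the reverse direction, and
  as subject-anchored because lesion severity is largely a property of
  the subject — trajectories then rise monotonically for most but not
  all subjects, as repeated-measures designs show.
- Module nodes get loading · (σ_stage · z + shift_stage) plus N(0,
  noise_sd²) noise, with loadings ≈ 1 for module genes and −0.8 for the
  repressor miRNAs (which therefore *fall* as their targets rise). The
  default σ_stage = (0.5, 1.5, 3.0) makes module variance and
  intra-module correlation rise across stages; shift_stage tracks
  σ_stage so the module's mean level and its fluctuation grow together
  and the deviation magnitude increases with stage for every severity
  draw.
- Boundary nodes (downstream of module targets) receive ρ_stage · z
  leakage with ρ = (0.6, 0.3, 0.1): boundary correlation falls as
  stages progress — the third DNB condition.
- 30% of the remaining mRNAs are generically stage-responsive
  (random-signed mean shifts growing with stage), providing the
  cohort-level differential expression that PERMANOVA and the ANOVA
  filter act on. noise_sd defaults to 0.3 so the planted module is
  moderately correlated (r ≈ 0.5) in the reference stage — detectable,
  not trivial, at n = 20 reference samples.
- Finally each feature is standardized against the reference stage.

What the generator does **not** emulate: probe-level microarray noise,
batch structure, missing values, genuine technical outliers, realistic
network topology (scale-free tails, dense TF co-regulation), or any
actual pigmentation biology. Consequently, passing recovery tests shows
the pipeline correctly extracts the designed signal from data satisfying
its model assumptions — not that it will perform equally on clinical
cohorts.

The recovery experiment (20 independent cohorts at the defaults) runs
the scoring path with outlier exclusion and the feature filter disabled:
the generator plants no technical outliers, and the 95% ellipses would
otherwise trim genuinely high-severity subjects, which is exactly the
right behavior for QC but the wrong experiment for measuring recovery.
Both preprocess detectors are instead calibrated on dedicated
multivariate-normal nulls (flag rate ≈ 1 − confidence).

## Numerical choices and degenerate inputs

- Fixed 6-significant-digit float formatting and (feature, sample) row
  ordering make all outputs byte-stable across identical runs.
- Pearson correlations are clipped to [−1, 1] against rounding; constant
  vectors are hard errors at the primitive level and logged skips at the
  pipeline level.
- Exhaustive PERMANOVA compares permuted F against observed F with a
  1e-12 slack to absorb float ties; degenerate within-group
  sums-of-squares of zero map to F = ∞ (or 0 when between-group is also
  zero).
- All randomness flows from explicit seeds (`numpy.random.default_rng`);
  the pipeline splits one root seed per stage. Same seed ⇒ identical
  networks, matrices, SSNs, scores and driver lists.
- Problem sizes in tests and the acceptance script (100-feature
  networks, 20-subject cohorts, 20 simulation seeds, ≤ 10-node oracle
  digraphs) were chosen so every experiment completes in seconds while
  keeping binomial/medians tolerances meaningful.

## Known limitations

- The SSN z-test is anti-conservative at the tails (see calibration
  caveat above); per-edge p-values are not multiplicity-corrected by
  default, matching common SSN practice, with an optional BH switch.
- mFVS favors highly connected nodes; low-degree but biologically
  pivotal regulators can be under-ranked. Out-degree ranking of drivers
  inherits the background network's ascertainment biases.
- The candidate rule (strict monotonicity + top decile) is one concrete
  instantiation of "rising stage-mean score"; real studies may need the
  exposed parameters tuned to reach a target list size.
- Correlation-based edges are not causal; the directedness comes from
  the background network's priors, not from the data.
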