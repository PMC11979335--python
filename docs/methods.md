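# Methods

This note documents the models, conventions and numerical choices behind
`fcnet`, in the spirit of a statistical package's methods appendix: what is
computed, under which assumptions, and where genuinely open design choices
were resolved.

## Synthetic cohort model

**Spatial structure.** Each group's generating correlation matrix is a
block-community matrix: `n_modules` contiguous blocks of regions with
correlation `within_r` (default 0.4) inside a block and `between_r` (default
0.1) across blocks, unit diagonal.  This is the simplest structure that gives
resting-state-like community organization — elevated clustering, short paths
— so that density-thresholded networks exhibit small-world topology and
degree-preserving null comparison is meaningful.  The defaults are typical
within-/between-network correlation magnitudes for band-passed regional BOLD
data; they are free parameters of the simulation, not estimates of any
particular scanner or population.

**Planted effect.** A list of region pairs (by default an 11-edge, 12-node
two-hub tree, the shape NBS analyses typically report) whose correlations are
shifted by −δ in the patient group only, clipped to (−1, 1).  If the shift
breaks positive definiteness, the matrix is projected to a nearby SPD
correlation matrix by alternating eigenvalue clipping (floor 1e−6) with
re-normalization to unit diagonal.  δ = 0 bypasses the shift entirely, so
null cohorts have *identical* group covariances by construction.  The
projection slightly redistributes a large planted shift over other entries;
recovery benchmarks therefore quote δ on the pre-projection correlation
scale.

**Temporal structure.** Subject time series are stationary Gaussian AR(1):
x_t = φ x_{t−1} + √(1−φ²) ε_t with ε_t ~ N(0, Σ_group), so the stationary
marginal covariance equals Σ_group for every φ.  The default φ = 0.4
(TR = 2 s) emulates the temporal autocorrelation that band-pass filtering
(0.01–0.1 Hz) leaves in BOLD data; filtering itself belongs to upstream
preprocessing and is not re-implemented.  The default series length is 150
timepoints (160 acquired volumes with the first 10 discarded).  Pearson
correlation is the natural estimand of this model, and the sample FC
converges to Σ_group as T grows (tested).

**Covariates.** Sampled per group, independently of the time series:
approximately normal variables (age, tissue volumes) as normals with the
published group mean/SD; skewed scores (education, MMSE, HAMA, HAMD,
SLEDAI-2k) as log-normals matched to the published median and quartiles
(σ = (ln q₃ − ln q₁)/(2 z₀.₇₅)), with ceiling-effect scales (MMSE) modelled
as `cap − deficit` with a zero-inflated log-normal deficit; treatment
categories at the published frequencies (controls always `none`, no
disease-activity score).  Mean framewise displacement, not tabulated in such
summaries, is log-normal around 0.08 mm in both groups — typical of
motion-screened resting-state cohorts.  Because covariates are independent
of group-specific connectivity, covariate-adjusted null calibration is exact
by construction.

**What the generator does not emulate** — haemodynamics, head motion beyond
a scalar covariate, scanner drift/physiological noise spectra, non-Gaussian
BOLD marginals, spatial autocorrelation beyond the block structure, and any
coupling between clinical covariates and connectivity.  Passing calibration
and recovery tests therefore validates the *statistical machinery* under a
clean generative model; they do not certify performance on real fMRI data.

## Connectome construction

Fisher z = arctanh(r) of the Pearson correlation between region pairs;
diagonal forced to 0; constant series are a hard error naming the region;
|r| = 1 between distinct regions is a hard error by default (clipping to
1 − 1e−12 is opt-in).  Density thresholding ranks upper-triangle entries by
|z| descending — negative and positive edges treated alike, since the sign
of weak/negative resting-state correlations has no agreed interpretation —
with a deterministic, seed-free tie-break by (|z|, then region-pair order),
and keeps the top round(D·N(N−1)/2).  Ranking |z| versus |r| is
observationally identical (arctanh is monotone).  Edge vectorization is the
row-major upper triangle with 0-based indices, recorded in an index file.

**Density-range admissibility.** A grid density is admissible when every
subject's σ exceeds 1.1 and the mean degree D(N−1) exceeds 2·ln N.  The
logarithm is natural: with ln, the canonical grid origin D = 0.10 at N = 116
satisfies the criterion (mean degree 11.5 > 9.51), whereas log₂ would
exclude it — i.e. only ln is consistent with the standard grid choice.  The
validator returns the longest contiguous admissible run (ties resolved
toward lower densities) and per-density diagnostics, and raises when the set
is empty.  The *pipeline* defaults to recording the diagnostics and
continuing on the full grid when the set is empty, because on small
simulated cohorts the min-over-subjects σ criterion can fail for benign
seeds; `strict_density_range: true` restores the hard failure.

## Graph indicators

Computed on the binary adjacency with scipy's sparse-graph shortest paths
(networkx supplies Brandes betweenness); the test suite checks all eight
indicators against exhaustive brute-force enumeration (Floyd–Warshall,
triangle counting, geodesic enumeration) on connected graphs with N ≤ 7.

* Cp: mean over all nodes of cᵢ = 2·triangles(i)/(kᵢ(kᵢ−1)), cᵢ = 0 for
  kᵢ < 2.
* Lp: mean shortest-path length over *reachable* ordered pairs.  Low
  densities routinely disconnect the graph; excluding unreachable pairs
  keeps Lp finite across the grid, matching common connectome-toolbox
  behaviour.  This convention changes λ relative to penalised alternatives
  and is therefore stated prominently.
* E_glob = ⟨1/d_ij⟩ over ordered pairs with 1/∞ = 0; E_loc and nodal local
  efficiency: global efficiency of each node's neighbour-induced subgraph
  (0 for < 2 neighbours); nodal efficiency NEᵢ = (1/(N−1)) Σ 1/d_ij.
* Betweenness: Brandes, normalized by (N−1)(N−2)/2.
* γ, λ: normalization by the *mean* (not median) Cp and Lp of 100
  degree-preserving random networks; σ = γ/λ is computed as that exact
  ratio, so the identity holds to machine precision.  Null networks use
  Maslov–Sneppen double-edge swaps with 10·E *attempted* swaps per network,
  seeded per (subject, density); rigid degree sequences (e.g. complete
  graphs) pass through unchanged, and graphs with < 2 edges return copies
  with a warning.
* AUC: trapezoidal rule over the (validated) density grid.

## Group inference

AUC group differences use OLS of the per-subject AUC on intercept + group
(patient = 1) + education + MMSE + GMV + WMV + mean FD + medication dummies
({gcs_alone, gcs_hcq, gcs_isa} against a reference pooling drug-naive
patients and untreated controls — the source analyses say only that
"medication" was regressed, so the encoding is a package choice).  In small
simulated samples a medication dummy can alias the group column (no
drug-naive patient drawn); aliased dummies are dropped with a warning rather
than failing, since the reference category is arbitrary.  Genuinely
collinear user covariates remain a hard error naming the columns.

Cohen's d defaults to the raw (unadjusted) group difference over the pooled
SD with (n₁−1, n₂−1) weighting.  Published effect sizes for
covariate-adjusted contrasts are not generally recomputable from the printed
t values (the t-to-d conversion gives systematically smaller numbers), so
the adjusted variant (d on nuisance-model residuals) is available via
`adjusted_d=True` and the discrepancy is documented rather than resolved.

Nodal comparisons are BH-FDR corrected across regions within each metric at
q < 0.05.  Demographic tables use the pooled two-sample t for approximately
normal variables, a tie-corrected Mann–Whitney z for skewed ones (exact
enumeration p when both n ≤ 8 and no ties), and Pearson χ² without
continuity correction for sex — the no-correction choice is validated by
exact reproduction of the published χ² = 1.441.  Kolmogorov–Smirnov
normality screening is a reporting aid; the t-versus-Mann–Whitney choice per
variable is a caller decision, not automated.

## Network-based statistic

Edge-wise statistics are the group-coefficient t from a vectorized OLS over
all edges, oriented one-sided per contrast; the two directions
(patient < control, patient > control) are run separately, each against the
primary threshold t₀ = 3.5.  An edge fitted exactly (zero residual variance,
e.g. constant across subjects) gets t = 0 rather than floating-point
noise/noise.  Components are extracted by union-find over suprathreshold
edges and verified against independent component labelling in tests.

Nuisance covariates are handled by Freedman–Lane permutation: fit the
reduced (nuisance-only) model once, permute its residual rows, add them back
to the reduced fit, refit the full model — the standard scheme for
GLM-based NBS; plain group-label permutation is available for
covariate-free designs.  The component statistic is extent (edge count) by
default, summed exceedance ("intensity") optionally.  FWER p-values use the
add-one convention p = (1 + #{null ≥ observed})/(1 + n_perm), bounded below
by 1/(n_perm+1), and are monotone in extent by construction.

Because extent is integer-valued, the attainable test sizes are discrete and
the test is mildly conservative: over 200 simulated null cohorts (20 + 20
subjects, 30 regions, t₀ = 3.0, 500 permutations) the empirical FWER at
α = 0.05 is ≈ 0.02–0.03.  The planted 11-edge subnetwork at δ = 0.4
(40 + 40 subjects) is recovered with essentially full edge sensitivity.
These simulation sizes (30 regions, hundreds of permutations) were chosen so
the whole calibration suite runs in minutes while keeping Monte-Carlo error
well inside the acceptance bands; the machinery is identical at 116 regions
and 10,000 permutations.

## Classification

Nested stratified cross-validation (default 10 outer / 5 inner folds).  Per
outer fold: edge statistics and suprathreshold components are computed on
the training subjects only; features are the Fisher-z values of the largest
component's edges (top-k = 10 edges by |t| as fallback when nothing survives
the selection threshold — the expected situation under the null); features
are standardized (training-fold statistics) and a linear-kernel SVC is
fitted, with C selected on the inner folds from {0.01, 0.1, 1, 10} (ties to
the smaller C).  Accuracy is the unweighted mean of per-fold accuracies;
class imbalance is handled by stratification, not reweighting.  Covariates
are *not* regressed out of features by default; train-fold-fitted
residualization is available (`remove_confounds=True`).  Reported
interpretability outputs are per-edge selection frequency across outer folds
and the mean |SVM weight| over folds where selected.

## Determinism and provenance

All randomness flows through one master seed via `numpy.random.SeedSequence`
spawning (per subject, per stage, per permutation block); derived integer
seeds stay below 2³¹.  Every pipeline artifact directory carries a manifest
with the configuration hash (excluding output location and log level), the
master seed and the package version; two runs with identical triples are
byte-identical, which the test suite asserts at the file level.

## Known limitations

* The generator's realism limits (above) mean calibration results transfer
  to real data only insofar as the GLM/permutation assumptions
  (exchangeability after nuisance removal, approximate normality of
  Fisher-z edges) hold there.
* Weighted-network metric variants, modularity/rich-club/assortativity, and
  voxel-level statistics are out of scope.
* The Lp reachable-pairs convention and the null-model rewiring effort
  (10·E attempts) are reproducibility-sensitive choices; alternatives alter
  λ and σ at low densities.
* Permutation p-values inherit extent discreteness; with few hundred
  permutations the attainable α levels are coarse.
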