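# Methods

`gamebrain` implements a data-driven association analysis between behavior
in 15 economic games and multimodal brain features, validated end to end on
a synthetic-study generator with a planted latent prosociality factor.
This note documents the model, the generator, the numerical choices, and
what the validation results do and do not show.

## The analysis model

Let X₁ (games), X₂ (cortical/subcortical structure), X₃ (functional
connectivity metrics) and X₄ (structural connectivity metrics) be
participants × variables blocks, each confound-residualized and reduced by
PCA. The sparse multi-set canonical correlation analysis (SMCCA) finds one
weight vector wᵢ per block maximizing the sum of pairwise between-set
covariances

    max  Σ_{i<j} wᵢᵀ XᵢᵀXⱼ wⱼ   s.t.  ‖wᵢ‖₂ ≤ 1,  ‖wᵢ‖₁ ≤ cᵢ,

the penalized multi-set formulation in which each block's within-set
covariance is treated as the identity (classical whitened CCA is out of
scope). The reported association strength is the sum of pairwise Pearson
correlations of the canonical variates uᵢ = Xᵢwᵢ.

**Optimization.** Block coordinate ascent: the update for block i
soft-thresholds aᵢ = Xᵢᵀ Σ_{j≠i} Xⱼwⱼ at the smallest level meeting the
lasso bound and renormalizes to unit length. The threshold level is solved
in closed form on the sorted-support pieces of the soft-threshold path
(each piece gives a quadratic in the threshold); when the bound is
unattainable because of tied leading entries, the nearest-feasible vector
is returned and the slack recorded. The objective is non-decreasing by
construction and asserted every sweep. Convergence: relative objective
change < 1e-6, at most 200 sweeps.

**Initialization.** Each wᵢ starts at the leading left singular direction
of its concatenated cross-covariance blocks [XᵢᵀXⱼ]_{j≠i}, computed by a
deterministic power iteration from the flat direction. This choice is
load-bearing: PCA score columns are mutually orthogonal, so after
standardization XᵢᵀXᵢ ∝ I and *every* direction is a leading singular
vector of Xᵢ — a within-set SVD start (available as `init="svd"`) is
numerically arbitrary there and frequently lands the ascent in noise-built
local optima. The cross-covariance start targets the shared variation
directly; with two sets and loose penalties it reduces to power iteration
on X₁ᵀX₂, whose fixed point is the rank-1 SVD oracle.

**Penalties.** Each cᵢ is a fraction f of √pᵢ, clipped to [1, √pᵢ]; one
shared fraction is tuned by default (per-set fractions are accepted).
`select_penalties` fits every grid fraction on the observed data and on
row-permuted replicates (each set permuted independently; the same
permutations reused across the grid) and picks the fraction maximizing
(z_obs − mean z_perm)/sd z_perm. The z statistic is the Fisher transform
of the *mean* pairwise correlation, sum_cor/n_pairs — the sum itself can
exceed 1 with more than two sets, where atanh is undefined. Default grid:
10 equally spaced fractions from 0.1 to 0.9.

**Significance.** The permutation test holds the games block fixed,
independently shuffles the participant rows of each brain block, and
refits with the penalties frozen at their observed-data selection
(two-stage procedure; a full re-selection mode exists for sensitivity
analysis). Both the plain proportion #{null ≥ observed}/n_perm and the
add-one variant (#{≥}+1)/(n_perm+1) are reported; the add-one form is the
one with the correct finite-sample null distribution and is used in the
calibration checks.

**Cross-loadings.** A cross-loading is the Pearson correlation of an
original residualized variable (not a PC score) with another block's
variate. Brain variables are loaded against the games variate; game
variables against each brain variate, averaged across the three brain
blocks with the per-block values retained. Class summaries report the mean
over regions with a 95% normal-approximation CI (mean ± 1.96·sd/√m; a
bootstrap is available) and the percentage of positive/negative regions,
zeros counting as positive. The global sign of the solution is fixed by
requiring prosocial-tagged game variables to load positively (one global
flip of all blocks, which changes no correlation).

## Confounds and reduction

All behavioral variables are residualized on age and sex; brain variables
additionally on handedness, intracranial volume and transmit reference
amplitude. The extended mode adds education (0/1, undergraduate degree),
income (1–7 ordinal treated as numeric), IQ and go/no-go false alarms on
top of — never instead of — the base set. Missing covariate values are an
error: the analysis is complete-case by design, with no imputation.

Each block is z-scored column-wise (configurable, default on — the blocks
mix mm, ratios and graph indices) and reduced by SVD-based PCA: 30
components for games, 60 for each brain block, with a robustness mode
re-running the fit at 70 and 80. Component signs are fixed by making the
largest-magnitude loading of each component positive, so downstream
results are reproducible across runs and platforms.

## Connectome metrics

Functional edges are Pearson correlations between regional time series;
structural edges are streamline counts with each row divided by its
waytotal, then symmetrized as (M + Mᵀ)/2. Each weighted network is
binarized at the threshold maximizing global cost efficiency
CE = E_glob − κ, where κ is the edge density and E_glob the mean of 1/d
over ordered node pairs (1/∞ = 0). Candidate thresholds are the sorted
unique absolute edge weights; on networks with more unique weights than
`max_candidates` the sweep runs over an even grid of network costs
(default range 1%–45%), which — like the exhaustive scan — depends only on
the weight ranks, so the procedure is invariant to monotone transformations
of the weights. Binarization keeps edges with |w| ≥ t (a positive-only
mode exists; by default negative correlations count by magnitude), ties in
CE break toward lower cost. During the sweep on large networks, E_glob may
be estimated from a deterministic evenly-strided subset of BFS source
nodes (default 24 of 360); all reported metrics are computed exactly on
the chosen graph.

On the binary graph, five nodal measures: clustering coefficient
2tᵢ/[kᵢ(kᵢ−1)] (0 when kᵢ<2), local efficiency (mean of 1/d over neighbor
pairs, distances inside the neighbor-induced subgraph), nodal path length
(arithmetic mean hop distance to *reachable* nodes — unreachable targets
are excluded and flagged rather than mapped to a pseudo-distance; a fully
isolated node yields NaN, which block assembly replaces by the
participant's largest finite path length, counted in the metadata),
degree, and unnormalized betweenness centrality (Brandes). Homotopic
interhemispheric connectivity is the weighted pre-threshold edge between
the same parcel in the two hemispheres (180 pairs per modality), the
operationalization consistent with a 5,441-column brain feature table:
4·360 cortical metrics + 41 volumes + 2·(5·360 nodal + 180 homotopic).

Shortest paths, betweenness, local efficiency and the threshold sweep run
on compiled (numba) BFS kernels; the test suite certifies all five
measures against independent brute-force enumeration (plain BFS, triangle
counting, predecessor-decomposition path counts) exactly on hundreds of
random small graphs, and against networkx on larger ones.

## The synthetic-study generator

The generator emulates the structure of a games + MRI study: one
standardized latent trait θ per participant drives every planted
association, with confound effects and noise on top. It defines the
validation conditions of the package; its defaults are fixed, not tuned
per experiment. Defaults: n = 217 participants (the analyzed complete-case
sample size), 360 cortical parcels (synthetic labels `L_P001`…`R_P180`;
real parcellation names are not reproducible here), the standard 41-entry
FreeSurfer aseg subcortical set, SNR 1 (planted effect per variable equal
to its noise SD).

* **Behavior.** Each of the 108 default decision variables (one per
  strategy-method grid cell; the enumeration is configurable) gets a
  latent value β·θ + confound effects + N(0,1), mapped to its legal range,
  clipped and rounded to the game's increment (JPY 100 or 10, 10% for
  trust-game returns); binary decisions threshold the latent propensity at
  0. β is positive for prosocial-tagged variables, negative for
  aggression/punishment, zero for "other".
* **Structure.** Parcel metrics are baseline + γ_r·θ + confounds + noise
  with region-varying γ magnitudes (uniform on [0.2, 1] of the planted
  scale, mirrored across hemispheres): thickness positive, myelin
  negative, neurite indices zero. The myelin signature shares 35% of its
  regional pattern with the thickness signature (with the opposite sign),
  so the two loading maps come out mildly anti-correlated — the direction
  expected when apparent myelin and thickness changes reflect common
  nonmyelinated tissue growth. Volumes: ventricles negative; corpus
  callosum, accumbens, amygdala, hippocampus, pallidum positive; others
  zero. Age, sex, ICV and transmit-amplitude effects are superimposed.
* **Functional connectivity.** Base correlation matrix with 12
  mirror-symmetric modules and elevated homotopic edges; θ additively
  strengthens homotopic (pair-specific weights) and within-module edges
  under heavy Gaussian edge noise (SD 0.1). Matrices are generated
  directly rather than via time series — the analysis consumes matrices,
  not series.
* **Structural connectivity.** Streamline counts are gamma-Poisson with
  dispersion shape 1 (CV ≈ 1); θ modulates homotopic (+80%·θ·pair weight)
  and within-module (+25%·θ) rates. The heavy overdispersion is essential:
  with near-deterministic Poisson counts the edge ranking is frozen across
  participants and the thresholded topology carries no signal. An optional
  long-range-shortcut mechanism exists but is off by default — experiments
  showed the cost-efficiency optimizer absorbs a strong cheap backbone by
  simply choosing a lower cost, inverting the intended integration effect.

With these defaults the planted directions propagate through the *entire*
pipeline (thresholding included) to the cross-loadings: interhemispheric
(both modalities) positive, myelin negative, thickness positive, nodal
path length negative in both modalities, ventricles negative, functional
clustering/local efficiency positive.

What the generator does **not** emulate: spatial autocorrelation on the
cortical surface, realistic fMRI noise spectra or motion artifacts,
distance-dependent tractography biases, non-Gaussian behavioral response
styles, or missing data. Passing recovery tests therefore demonstrates
that the pipeline is correct and sensitive under a faithful latent-factor
data-generating process — not that the effect sizes or canonical
correlations reported on synthetic data transfer to real cohorts (at SNR 1
with 108 consistent behavioral indicators the latent trait is estimated
almost noiselessly, so synthetic canonical correlations approach 1).

## Reproducibility and problem sizes

A single master seed expands into named per-stage substreams
(`SeedSequence([seed, crc32(stage)])`), so identical seeds give
bit-identical studies and byte-identical reports, and stages can be re-run
in isolation. Validation sizes used by the test suite and the acceptance
script: 200 random graphs for oracle equivalence; 50 random instances for
the SVD oracle; 200 null studies (n = 100, n_perm = 199) for calibration;
12 full-scale planted studies (n = 217, seeds 1–12) for sign and signature
recovery, the first 5 reused for the across-K concordance check; the
acceptance script runs one fully tuned study plus 3 recovery replicates
and 60 null studies. These are the package's documented validation sizes;
the statistical thresholds they are checked against (95% sign recovery,
median signature correlation 0.7, null rejection in [0.02, 0.09],
concordance 0.9) are fixed properties of the procedure.

## Known limitations

* The cost-grid threshold sweep evaluates at most `max_candidates`
  candidate costs; on large networks the CE optimum is located to within
  the grid resolution, not exactly.
* Nodal path length uses the arithmetic mean over reachable targets; a
  harmonic-mean variant of integration is not separately exposed (global
  efficiency covers that notion at the network level).
* Only the first canonical component is studied; deflation for further
  components is implemented (residualizing each block on its earlier
  variates) but not exercised by the validation suite.
* The permutation scheme assumes exchangeable participants; family or
  batch structure would require restricted permutations, which are not
  implemented.
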