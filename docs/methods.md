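# Methods

## Model and procedure

`mimfa` handles *row-wise* missingness in multi-table analysis: an
individual is either fully observed or fully absent in a given table, and
every individual is observed in at least one table (an individual missing
everywhere cannot receive hot-deck donations and is rejected at load).
Cell-level missingness and categorical variables are out of scope. The
missingness mechanism is assumed ignorable (rows missing completely at
random given the strata); nothing in the pipeline models an informative
mechanism.

The analysis chain is: stratified hot-deck multiple imputation → MFA per
completion → STATIS compromise → uncertainty regions. Each stage is exposed
separately (`hotdeck`, `mfa`, `statis`, `pipeline`, `uncertainty`) so the
intermediate objects (donor assignments, per-completion configurations, RV
matrix, trajectories) can be audited.

### MFA conventions

* Variables are centred, and by default standardised to unit variance
  within each table, using the population standard deviation (ddof = 0).
  Whether the original analyses standardised within tables is not
  documented; standardisation is the common default of MFA implementations
  for quantitative groups, so it is the default here and a
  `PreprocessSpec(scale_unit_variance=False)` toggle covers the covariance
  convention.
* PCA is computed by SVD with uniform row weights 1/I; eigenvalues are
  reported on the covariance scale (singular value² / I), the French-school
  convention. Scores are principal coordinates (U·s), so column variances
  equal the eigenvalues.
* Sign convention: per component, the loading of largest absolute value is
  made positive (ties broken by the earliest column), giving deterministic
  output across BLAS implementations.
* If the requested dimensionality d exceeds the numerical rank, the
  configuration is padded with zero-eigenvalue components and a warning is
  emitted, keeping downstream shapes stable.

### Hot-deck imputation

Donor pools are per (table, stratum): all observed individuals of the
recipient's stratum in the table where the row is missing; a recipient
missing from several tables draws an independent donor in each. Draws are
with replacement across recipients; a completion is a full assignment map,
and M completions must have pairwise-distinct maps. Distinctness is
enforced on assignments, not on value matrices — two distinct assignments
could in principle produce equal matrices if two donors had identical rows,
which has probability zero for continuous data. The count of distinct
completions is M_total = ∏ over recipients |pool| (the natural product
law; each recipient's donor is chosen independently).

Duplicates are handled by rejection sampling with a cap of 100·M draws,
which is unbiased among distinct maps and cheap whenever M ≪ M_total; the
pipeline refuses M > M_total up front. All draws come sequentially from one
seeded generator, so for a fixed seed the first M′ completions of a longer
run equal a direct M′ run. This prefix stability is what implements the
*nested* collections of the stability procedure (below) without extra
bookkeeping.

### STATIS

Configurations enter STATIS as-is (MFA scores are already centred; their
cross-products are rotation/reflection-invariant, which is the point of
working with Wₙ = FₙFₙᵀ). No re-normalisation of the Wₙ traces is applied:
the RV matrix is scale-invariant, so the weights αₙ are unaffected, and the
compromise inherits the common scale of the M configurations. α is the
leading eigenvector of the RV matrix, sign-flipped so its sum is positive
(the Perron direction is defined up to sign), clipped at zero for numeric
noise, and normalised to sum 1. Compromise scores use principal-coordinate
scaling (eigenvector × √eigenvalue). Trajectories are the classical
supplementary projections Wₙ·U_c·Λ_c^(−1/2); their α-weighted average
reproduces the compromise exactly, which the tests assert.

### Choosing M

If M_total ≤ 50 every completion is used (M = M_total) and the procedure
short-circuits. Otherwise, for each of N replicates, nested collections at
levels M₀ < M₁ < … are grown and rₙˡ = RV(compromise at Mₗ, compromise at
Mₗ₋₁) recorded; the curve reports the per-level mean and SD. Convergence is
declared when successive means differ by less than `tol` (default 0.01, two
decimals — matching the precision at which RV values are usually read);
the criterion itself is a package choice, since no standard threshold
exists. Defaults: d = 2 (all comparisons here are two-dimensional), levels
10/20/30, N = 5. These are desk-scale sizes chosen so the whole procedure
runs in seconds on the bundled designs; N can be raised for smoother
curves.

### Uncertainty regions

Each individual's M projected positions (first two compromise dimensions)
are summarised by (a) the normal-theory confidence ellipse
{x : (x−μ)ᵀΣ⁻¹(x−μ) ≤ χ²₂(level)} with area π·q·√det(Σ), and (b) the convex
hull with shoelace area. The ellipse is a visual uncertainty guide, not a
formal coverage statement about the true configuration: the M points are
projections of dependent re-analyses, not an i.i.d. sample. Degenerate
cases: coincident points give zero-area regions; M < 3 skips ellipses (a
covariance needs 3 points) but keeps hulls; collinear hulls degenerate to
segments of zero area.

### Baselines and evaluation

* **MVI-MFA**: missing rows replaced by observed per-variable means, then
  plain MFA.
* **RI-MFA**: an EM-style loop on the weighted merged table — initialise
  missing cells with column means, then alternate a rank-`ncp` SVD
  reconstruction with refilling the missing cells, recomputing centring,
  scaling and table weights each pass, until the imputed cells change by
  less than `tol` (relative) or `max_iter` is hit (then a warning). With
  `shrinkage` on (default) each retained singular value is damped by
  (λ_k − σ̄²)/λ_k, σ̄² the mean discarded eigenvalue — the regularization
  that keeps small signals from being overfit. `ncp=0` reduces exactly to
  MVI. `freeze_preprocess=True` fixes the preprocessing at the initial
  fill, which makes the loop a textbook EM with a provably nonincreasing
  observed-cell objective (the property tests use this mode; with
  re-estimated scaling and weights the objective is only empirically well
  behaved). This comparator is a generic re-creation of regularized
  iterative MFA imputation, not a port of any specific implementation.
* **Procrustes alignment**: closed-form ordinary Procrustes (translation,
  orthogonal transform including reflection, isotropic scale) used before
  visual comparison; the RV coefficient itself is invariant to similarity
  transforms, which the tests exploit to validate both implementations
  against each other.
* **ncp selection for RI**: when the truth is known the benchmark picks
  `ncp` from a small grid to best match the true configuration (`ncp_rule
  ="best"`). The selection rule is exposed (`best|worst|fixed`) because the
  opposite reading ("minimise the RV") appears in the literature this
  design follows; "best" treats that as the intended meaning, and the flag
  lets a user reproduce either.

## Synthetic data

The generator emulates only the *shape* of the two motivating designs —
their strata, sample sizes and table widths — not the correlation structure
of real omics data. Each stratum gets a 2-dimensional latent position
g_s ~ N(0, I); table j loads it through a sparse loading matrix (half the
variables, Gaussian loadings) scaled by `effect_size`; i.i.d. N(0,
noise_sd²) noise is added. Defaults effect_size = 1, noise_sd = 1 give a
clearly recoverable but noisy stratum structure (per loaded variable the
signal and noise variances are comparable), which is the regime in which
comparing imputation methods is informative — at zero effect all methods
are equally lost, at huge effect all are equally fine.

Presets: `liver_preset` (8 strata × 8 individuals; 300 + 10 variables — the
wide table is scaled down from thousands of transcripts for desk-scale
runtime, keeping the wide-vs-narrow asymmetry) and `nci60_preset` (9
cancer-type strata of sizes 8/6/7/9/6/8/6/2/8; 150 + 30 variables,
preserving the transcriptome:proteome width ratio).

Missingness scenarios remove a stated number of rows per stratum per table,
disjointly by default — the only reading under which the seven published
per-stratum case counts for strata of eight (56, 168, 168, 280, 420, 560,
280) are all reproduced by C(n,t₁)·C(n−t₁,t₂). The NCI-60-style two-table
pattern uses the stated per-stratum removal counts; its published
per-stratum case counts do not follow from any binomial reading of the
stated stratum sizes and are not asserted. Because passing tests rest on
this generator, they demonstrate correctness of the machinery and the
qualitative orderings (MI ≥ MVI; decline with missingness; uncertainty
growth), not performance on any real dataset.

## Known limitations

* Donor pools require at least one observed same-stratum individual per
  table; a fully missing (table, stratum) block is an error, not a
  fallback.
* Empirical RV values on the real liver-toxicity and NCI-60 datasets are
  not reproduced here: they depend on external downloads and unrecorded
  random removals.
* The compromise is computed for a fixed d chosen a priori; no automatic
  dimensionality selection is attempted.
* Hot-deck imputation reuses observed rows verbatim, so imputed values are
  always realistic but never novel; with tiny donor pools the M completions
  can be highly correlated and the uncertainty regions correspondingly
  optimistic.
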