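# Methods

This note documents the models implemented in `sbmtools`, the parameter
choices that matter, what the phantom does and does not emulate, and the
numerical decisions taken where the design was genuinely open.

## Generative model and the phantom

Source-based morphometry assumes each participant's masked gray-matter
density map is approximately a linear mixture

    x_i = baseline + Σ_k a_ik · s_k + ε_i,

with K spatial sources s_k shared across participants, loadings a_ik,
and voxel noise ε. The phantom (`sbmtools.phantom`) instantiates exactly
this model so that every downstream stage has a known ground truth:

- **Sources** are isotropic Gaussian blobs (σ = `source_radius_vox`
  voxels, default 2.5; amplitude 1.0) at random centers, accepted only
  while every pairwise spatial correlation stays below 0.2 (rejection
  sampling). Blobs emulate the anatomically clustered, compact
  components structural ICA tends to produce; they make no attempt at
  cortical anatomy.
- **Loadings** are unit-variance Laplace draws. Super-Gaussian loadings
  are deliberate: with Gaussian loadings the mixture would be
  rotationally invariant and ICA unidentifiable.
- **Group effect**: designated sources' loadings are shifted between the
  autism-like and control-like groups. Defaults −0.36 and −0.32 SD on
  the first two sources, matching the size of effects this kind of
  analysis is designed to detect (|d| ≈ 0.3–0.4); those effects need
  several hundred participants to survive FDR, and the phantom
  reproduces that behavior.
- **Covariates**: age, sex, FSIQ and site tilt every loading with
  standardized slopes (default 0.1 each), so covariate adjustment in the
  GLM is load-bearing rather than decorative. Marginals mirror a
  realistic cohort: ages 6–30 y, male fraction 0.729/0.647 in the
  autism/control groups, FSIQ means 99.4/104.9, ADHD comorbidity
  0.465/0.104, five sites, autism fraction 347/599.
- **Behavior**: eight symptom scores (five examiner-rated subscales,
  three parent-rated totals) are generated as y_q = a·u + noise, where u
  is a fixed combination of a designated loading subset and the common
  coefficient a is solved from the requested population canonical
  correlation r₀ (default 0.7): with Q scores and noise SD s,
  r₀² = t/(1+t) with t = Q·a²/s². Symptom noise is independent across
  scores; the phantom does not model the covariance structure among real
  symptom scales, which is unknown.
- **Densities** are `baseline` (default 1.0) plus the mixture plus
  Gaussian voxel noise (default SD 0.25), clipped at zero. With the
  default baseline the clip is essentially never active, which keeps the
  mixture linear; setting `baseline=0, clip_negative=False` yields an
  exactly rank-K matrix, used by the algebraic tests.
- **Missingness** (`generate_missingness`) masks ⌊fraction·n⌋ rows'
  behavior scores completely at random (rounding toward completeness, so
  a 0.441 fraction of 347 rows leaves 194 complete cases); diagnosis and
  covariates are never masked.

Everything is deterministic given the spec seed; `.nii.gz` outputs are
written with a fixed gzip mtime so repeated runs are byte-identical.

Because the phantom satisfies the model assumptions by construction,
passing tests demonstrate correctness of the *machinery* — they say
nothing about registration error, segmentation bias, scanner effects, or
non-linear brain-behavior relations in real data.

## Preprocessing

Smoothing uses a separable discrete Gaussian (σ_vox = FWHM /
(2√(2 ln 2) · voxel size), truncated at 4σ) with **reflective** boundary
handling, which preserves mean intensity near edges; FWHM 0 is the
identity. The homogeneity QC computes each subject's mean Pearson
correlation with all other maps and flags values below
mean − 3·SD; constant maps have undefined correlations and are flagged
distinctly. QC runs on smoothed data by default (mirroring
sample-homogeneity checks that operate on processed maps); the pipeline
exposes the smoothing FWHM, so unsmoothed QC is one config line away.

## Spatial ICA

The subject × voxel matrix is voxel-wise demeaned (variance
normalization is available but off by default), reduced by SVD to the
model order, and the whitened spatial components are rotated by
fixed-point ICA: log-cosh contrast, symmetric decorrelation, tolerance
1e−6, at most 1000 iterations, best of 5 random restarts by final
contrast. Components are z-scored spatially; ICA's two ambiguities are
fixed by convention — each component is sign-flipped to positive spatial
skewness, and components are ordered by loading variance. The
reconstruction `loadings @ sources + mean_map + subject_offset` equals
the rank-d PCA projection exactly (ICA is a rotation of the whitened
subspace), which the tests assert.

Model order can be estimated from the eigenspectrum by (a) a cumulative
variance threshold or (b) the Laplace approximation to the PCA model
evidence (Minka's criterion), treating voxels as samples. The evidence
calculation assumes spatially white residual noise: **order estimation
is therefore run on unsmoothed maps** in the pipeline. On smoothed maps
the spatially correlated noise inflates trailing eigenvalues and the
criterion grossly over-estimates the order.

The same phenomenon affects deliberate over-factoring: when the model
order exceeds the true source count and the noise is smooth, fixed-point
ICA splits each true source across two components (we verified an
independent FastICA implementation behaves identically). The model-order
robustness experiment (orders 10 vs 5 on a K=5 phantom) is accordingly
run on unsmoothed maps, where both orders recover every planted source
at |r| ≥ 0.97 and cross-order matching is essentially perfect. This is a
known limitation to keep in mind when factorizing heavily smoothed data
at generous orders.

Component correspondence between decompositions uses the Hungarian
assignment maximizing total |spatial r| (sign- and permutation-proof);
pairs under the `min_abs_r` threshold are reported unmatched.

## Component GLM and FDR

Each loading column (standardized to unit variance for comparable β) is
fit by OLS on intercept + group (control = 0, clinical = 1) + covariates;
site enters by reference dummy coding, missing rows are removed listwise
per analysis, and rank deficiency is reported naming the collinear
columns. The group effect is summarized by β, t (df = n − rank), the
two-sided p, and Cohen's d = t·√(1/n₁ + 1/n₂) — the covariate-adjusted
form, which equals the classical d when no covariates are present.
Sensitivity variants (ADHD covariate, IQ-restricted subset, age² and
interaction terms) reuse the same design builder with different term
sets rather than separate code paths.

Multiple comparisons across components use the Benjamini–Hochberg
step-up at q = 0.05 (the standard FDR procedure); the implementation is
cross-checked against statsmodels in the tests and its calibration is
verified by simulation (false-rejection proportion ≤ q + 2·MC-SD under
the global null).

## Voxelwise inference

TFCE integrates e(h,v)^E · h^H over suprathreshold heights with
E = 0.5, H = 2, 26-connectivity, and dh = max/100 — the canonical
published defaults — using `scipy.ndimage.label` per threshold step;
two-tailed maps are enhanced as +map and −map separately and recombined
with sign. The implementation matches a naive per-voxel threshold-sweep
oracle to better than 1e−9.

Permutation inference uses the Freedman–Lane scheme: outcomes are
residualized on the nuisance-only model, residual rows are permuted, and
the full model is refit — plain label shuffling is not exchangeable when
covariates are present. FWE p per voxel is (1 + #{null max ≥ observed})
/ (n_perm + 1) with the null built from the maximum two-tailed |TFCE|,
so the smallest attainable p is 1/(n_perm+1).

## CCA

CCA is solved by QR of each z-scored block and SVD of Qx'Qy — exact,
deterministic, and identical (to 1e−6) to iterative reference
implementations; the first canonical correlation equals
√λ_max(Σxx⁻¹ Σxy Σyy⁻¹ Σyx) to 1e−8. Columns are z-scored because
symptom scales have heterogeneous units. No regularization is applied by
default (faithful to plain CCA at n ≫ p); ill-posed refits fall back to
a pseudo-inverse and are flagged. Covariates are not regressed out
before CCA by default; a residualization hook exists for sensitivity
use. When n does not exceed the larger block size the fit warns —
in-sample canonical correlations of 1 are then guaranteed.

"Corrected" coefficients are **structure coefficients**: the correlation
of each original variable with its own set's canonical variate. They are
invariant to collinearity-induced arbitrariness in raw weights (two
collinear variables receive equal corrected values) and drive the
per-variable contribution ranking in reports.

Significance of the main (first) mode is tested by permuting behavior
rows and recomputing the first canonical correlation (permuting one
block suffices under exchangeability), with the conservative +1-count
estimator, compared against 0.05/n_modes; other modes are reported
descriptively. Permuting rows of the precomputed orthonormal basis Qy is
exact here because a permutation matrix preserves column orthonormality,
which makes 10,000 permutations cheap.

Reliability: leave-one-out refits record the sign-aligned correlation of
each fold's main-mode weights with the full-sample weights (brain and
behavior sides separately); the subsampling curve repeats this for
random subsets of increasing size. Under a strong planted mode the LOO
means exceed 0.99; in the ill-posed pure-noise regime
(pₓ + p_y > n − 1, where the "mode" is an arbitrary direction in a
subspace intersection) they collapse to ≈ 0.3–0.4.

## Cohort tables

Two-sample t tests are computed from mean/SD/n summaries: pooled
(Student, df = n₁+n₂−2, the default — it reproduces printed cohort
tables exactly) and Welch (Satterthwaite df) — some published subgroup
rows are better matched by Welch, so both are exposed. The 2×2
chi-square uses the closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) without
continuity correction by default (again matching printed tables), with
the Yates variant available.

## Validation problem sizes

The acceptance experiments use: 50 phantom seeds (20×24×20 grid, N=200,
K=5) for ICA recovery; one phantom for cross-order matching; 600
simulations (16³ grid, N=100, K=20, no group effect) for FDR
calibration; 200 null runs × 500 permutations for CCA type-I error; 30
seeds (N=300, K=20) for CCA power; and one N=300 phantom for LOO and
subsampling. These sizes give Monte-Carlo standard errors comfortably
below the margins being tested while keeping a full validation run
around a minute.

## Known limitations

- The phantom's sources are compact blobs with independent noise; it
  does not simulate registration error, scanner/site intensity effects
  beyond a loading shift, realistic anatomy, or correlated symptom
  noise.
- Laplace order estimation and over-factored ICA both degrade on
  spatially smoothed noise (see above).
- The voxelwise module implements no variance smoothing or tail
  approximation; very small FWE p-values require correspondingly many
  permutations.
- CCA is unregularized; with pₓ approaching n the in-sample correlation
  is upward biased, which is exactly why the permutation test and the
  stability diagnostics are part of the pipeline rather than optional
  extras.
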