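# Methods

## The benchmark in one paragraph

Classifying two well-separated brain states (eyes open vs eyes closed) from
resting-state functional connectivity is a controlled setting for asking
how much the processing pipeline — confound regression, connectivity
estimator, parcellation — matters. `fcbench` implements the full chain as a
library and validates it on synthetic data in which the "right answer" is
known: which edges differ between states, which nuisance series were mixed
into the signal, and how strongly each subject moved.

## Synthetic data model

One scan of `T` volumes over `R` regions is

    y_t = scale · ( L z_t + c · w m_t + c · a_s · Λ x_t + ε_t )

* `L L' = Σ_state + β u_s u_s'` — the state covariance plus a rank-one
  subject effect. Σ_EO is a 3-factor correlation-like SPD matrix (factor
  loadings 0.8·N(0,1), uniform diagonal noise, normalized to unit
  diagonal); Σ_EC shifts `n_diff_edges` upper-triangle entries by
  ±`effect_size`. Differential edges are placed on node-disjoint pairs with
  weak baseline correlation so the perturbation has spectral norm equal to
  the effect size; if positive definiteness would still need a diagonal
  shift τ = max(0, 1e−6 − λ_min) of ≥ 10% of the effect, the configuration
  is rejected outright (the repair, when it fires, only shifts the
  diagonal). The subject effect β = 0.1 gives stable between-subject
  differences — the variance component that makes ICC > 0.
* `z_t` — unit-variance AR(1) latent draws, φ = 0.3 (configurable; real
  autocorrelation is unknown, this is a mild conventional value).
* `m_t` — mean frame-to-frame motion increment of the simulated realignment
  parameters (AR(1)-increment random walks scaled to the subject's
  amplitude; rotations at amplitude/100 rad so translations and rotations
  contribute comparably to FD). Because the 12/24-HMP blocks contain the
  backward-difference derivative columns, `m_t` lies exactly in their span:
  motion denoising can in principle remove the contamination completely.
* `x_t` — unit-variance AR(1) physiological components mirroring the
  aCompCor/tCompCor confound columns, coupled with strength proportional to
  the subject's relative motion amplitude `a_s`. That choice (high-motion
  subjects are also high-artifact subjects) is what makes QC-FC respond to
  component regression and not just to motion regression, as it does on
  real data.
* `ε_t` — white noise, σ = 0.05. `scale` is 1.0 for site A and 1.2 for
  site B (a simple multiplicative scanner effect; the shorter-TR site also
  has more volumes, so cross-site transfer is nontrivial in both SNR and
  scaling).

Subject motion amplitudes are log-normal around 0.1 mm (σ = 0.4 log units),
matching the order of magnitude of mean framewise displacement in typical
healthy-adult resting data.

**Site geometry.** Site A: 84 subjects × (EC, EO) sessions, TR 2.5 s, 120
volumes. Site B: 48 subjects × 3 sessions, TR 2.0 s, 240 volumes; session 1
is always EC, sessions 2–3 are EO/EC counterbalanced by subject parity
(even-indexed subjects see EO second). Desk-scale runs use 20 + 12 subjects
with the same geometry; all defaults here are the package's study
conditions, chosen once.

**What the generator does not emulate:** voxel-level BOLD, hemodynamics,
slice timing, spatial misregistration, non-Gaussian artifacts, scanner
drift beyond the cosine-basis regime, or realistic ICA-AROMA spatial
classification (component time series and noise flags are generated
directly). Passing tests therefore demonstrate internal correctness and
qualitative behaviour of the metrics, not performance figures transferable
to real data.

## Coverage

Per-subject masks keep voxels with temporal-mean signal ≥ 0.6 × the global
reference, where the reference is the mean over nonzero voxels (robust to
zero padding; computed on the temporal-mean image). The consensus mask
keeps voxels present in ≥ 50% of subject masks (inclusive), and parcels
with < 10% of voxels in the consensus (strict) are rejected.

## Denoising

Sixteen strategies: eight base recipes (24HMP; aCompCor ± 50% variants with
12/24 HMP; tCompCor + aCompCor(50%) + 24HMP; non-aggressive / aggressive
ICA-AROMA + 10-component aCompCor) and the same eight with four
global-signal regressors. Every design carries an intercept and a
discrete-cosine basis (cutoff 128 s, `floor(2·T·TR/cutoff)` columns).
Derivatives are backward differences with a leading zero. The fourth GSR
column is literally the derivative of the squared global signal. Aggressive
AROMA puts the noise-component columns in the design; non-aggressive AROMA
fits all components jointly and subtracts only the noise columns'
contribution before the remaining design is residualized. Rank-deficient
columns are dropped in QR pivot order and reported. Regressors are used
unstandardized; OLS residuals are unaffected by column scaling.

## Connectivity

All measures run on Ledoit–Wolf shrinkage covariances of the cleaned
series (empirical covariance available by flag). Partial correlation is
−P_ij/√(P_ii P_jj) from the precision matrix, diagonal 0. The graphical
lasso solves the off-diagonal-L1-penalized log-det program by ADMM
(closed-form eigenvalue update / soft-thresholding split, tolerance 1e−9 on
primal and dual residuals) on the correlation-scaled input with default
α = 0.05; converged solutions satisfy the KKT system to ~1e−9, and the
solver's objective agrees with an independent coordinate-descent
implementation to ~1e−10. Tangent-space FC whitens each covariance by
G^(−1/2) at the affine-invariant Fréchet mean G of the *training*
covariances (fixed-point iteration, tolerance 1e−8, cap 60; log-Euclidean
mean available as fallback) and takes the matrix logarithm. The fitted
reference records the scan ids it saw, so leakage is auditable. Edge
vectors are the row-major upper triangle excluding the diagonal.

## Quality and reliability metrics

* FD: Power convention, 50 mm rotation radius. Relative RMS displacement:
  Jenkinson convention, 80 mm sphere; the scan-level scalar is the mean
  over volumes 2..T. (The formulas are conventions of the preprocessing
  ecosystem; both radii are arguments.)
* QC-FC: per-edge |Pearson r| across subjects between edge weight and mean
  relative RMSD, summarized as the mean over defined edges; zero-variance
  edges are excluded and reported as NaN.
* Strategy similarity: within each subject, the correlation matrix of the
  flattened FC vectors across (strategy, state) conditions, averaged over
  subjects.
* ICC: ICC(3,1), ICC(2,1), ICC(1,1) from the two-way mean squares (BMS,
  WMS, RMS, EMS), no silent clipping, degenerate inputs raise. Edge masking
  keeps the `ceil(0.05·E)` edges with largest |group-mean| value — absolute
  value because tangent/partial edges are signed; ties break by index order.
  On the synthetic study the two repeated-EC scans of the three-session
  site form the n×2 rater table (each subject has exactly one later EC
  scan under counterbalancing, so the two session-pairings collapse into
  one table).

## Classification

Edge vectors → PCA fitted on training scans only, retaining the smallest
component count reaching 95% of training variance → logistic regression
(L2, C = 1.0, LBFGS, ≤ 1000 iterations) → accuracy at 0.5 (no calibration),
rank-statistic ROC-AUC with average-rank ties, per-scan Brier loss
aggregated per subject. Splits are always at subject level. Cross-site
trains on all usable source-site scans and tests on the full target site;
few-shot adds both scans of `n_target` randomly drawn target subjects to
the training set (fresh draw per iteration, seeds = base + i, default 15
iterations). At the three-session site each subject contributes the EO
scan and the session-1 EC scan, so 48 source subjects yield 96 training
samples and 84 target subjects with 20 drawn yield 40 train / 128 test.

## Factor inference

For a factor-level contrast, all pipeline pairs differing only in that
factor are matched; per-subject mean Brier differences are averaged over
matched pairs and tested by sign-flip randomization (statistic = mean;
exact enumeration of all 2^n flips for n ≤ 12, otherwise 5000 draws with
the add-one p-value correction, which guarantees p > 0). BH-FDR is applied
within each factor. With 4 FC measures, 4 atlases, 8 strategy families and
the GSR flag tested in both transfer directions, the design yields
(6 + 6 + 28 + 1) × 2 = 82 comparisons.

## Stable edges

FC is estimated once on the pooled dataset and reused across 1000 (desk
default 100) site-stratified 80% subsamples; per-site counts use
round-half-up (84, 48 → 67, 38), and a selected subject contributes both
scans. Each iteration fits PCA(95%) + LR and converts weights to forward
activation patterns via `a = V (λ ⊙ w_pca)`, which equals Σ_x·w whenever no
variance is discarded. An edge is stable when its activation sign is
preserved in ≥ 80% of iterations *and* it ranks in the top k by
|activation| in ≥ 50% of iterations; k = 500 at a ~200-region parcellation
is ~3% of edges, so desk-scale runs use k = ceil(0.03·E). The top-k
frequency threshold (50%) is the package's aggregation choice; it is
exposed as `freq_thresh`. Because consecutive subsamples share 80% of the
data, a few noise edges can be persistently selected under a null effect;
the joint criteria keep that false-positive set at ~1–2% of edges in the
desk-scale null simulation.

## Numerical and design choices

* State-separation comparison across measures uses 1 − mean within-subject
  EO/EC edge-vector correlation (the similarity-matrix construction), which
  is scale-free; raw edge-vector distances are not comparable across
  representations whose scales differ.
* The sign-flip type-I calibration uses 20 subjects × 1000 permutations ×
  1000 replicates; the binomial null band for the zero-effect classifier
  uses one iteration's test-set size as the effective n, since the 15
  few-shot iterations share test subjects.
* Desk-scale defaults everywhere: 20 regions, 5 planted edges at
  |Δ| = 0.3, 20 + 12 subjects, 100 stability iterations. These sizes keep
  the full test suite and the acceptance run fast while leaving every
  qualitative property (QC-FC ordering, ICC masking gain, tangent > partial
  separation, > 0.8 cross-site accuracy, ≥ 0.7 stable-edge precision and
  recall) comfortably detectable.
* Degenerate inputs: all-zero sign-flip differences give p = 1; zero-variance
  ICC tables, all-zero coverage images, constant time-series columns and
  asymmetric FC matrices raise with the offending region/parcel named.

## Known limitations

* ICA-AROMA component classification is out of scope; noise flags are
  inputs. On real confound tables the package trusts fMRIPrep's columns.
* The generator's site effect is a pure scale factor; nonlinear scanner
  effects, susceptibility dropout and coverage differences between sites
  are not modelled (coverage is exercised on its own label-volume fixture).
* Real-data headline numbers (QC-FC magnitudes, masked ICC levels,
  cross-site AUCs of specific atlas/strategy cells, stable-edge counts of a
  200-region parcellation) are properties of the two real datasets and are
  not reproduced by the synthetic study; the package reproduces the
  procedures and their qualitative behaviour.
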