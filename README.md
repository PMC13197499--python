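# fcbench

Benchmarking machinery for resting-state functional-connectivity (FC)
processing pipelines, built around a within-subject brain-state contrast:
classifying eyes-open (EO) versus eyes-closed (EC) resting scans from region
× region connectivity matrices.

Decisions made while turning fMRI time series into connectomes — which
nuisance regressors to remove, which connectivity estimator to use, which
parcellation — change the resulting classifier, its reliability and its
biomarkers. `fcbench` implements every stage of that benchmark as a tested
library, exercised end to end on a synthetic two-site dataset with known
ground truth (planted differential edges, motion contamination, latent
physiological noise), so that each quality metric and inference procedure
can be validated against what was actually planted.

## What is implemented

* **synthetic** — a two-site EO/EC generator. One site mimics 84 subjects ×
  2 sessions (TR 2.5 s, 120 volumes), the other 48 subjects × 3 sessions
  (TR 2.0 s, 240 volumes; first session EC, the rest counterbalanced).
  Scans follow `y_t = L z_t + c·w m_t + c·a_s Λ x_t + ε_t`: state covariance
  through a Cholesky factor `L`, motion increments `m_t` coupled by
  per-region weights `w`, latent physiological components `x_t` with
  loadings `Λ`, all emitted alongside fMRIPrep-style confound tables.
* **coverage** — voxel-coverage masking (signal ≥ 0.6 × global reference per
  subject, ≥ 50% consensus across subjects) and rejection of parcels with
  < 10% covered voxels.
* **denoise** — the 16 confound-regression strategies (12/24 head-motion
  parameter expansions, aCompCor with 10 components or at 50% explained
  variance, tCompCor, aggressive/non-aggressive ICA-AROMA, 4 global-signal
  regressors), discrete-cosine drift basis, OLS residualization.
* **connectivity** — Pearson correlation, partial correlation, graphical
  lasso (own ADMM solver of the L1-penalized log-det program), and
  tangent-space parametrization at the affine-invariant Fréchet mean, with
  a strict train-only fit contract and provenance recording.
* **qc** — framewise displacement (Power), relative RMS displacement
  (Jenkinson, 80 mm sphere), QC-FC (|r| between edge weights and subject
  motion), within-subject strategy-similarity matrices, and ICC(1,1),
  ICC(2,1), ICC(3,1) from first-principles ANOVA mean squares with
  95th-percentile edge masking.
* **classify** — PCA retaining 95% of training variance + L2 logistic
  regression (C = 1.0, LBFGS, ≤ 1000 iterations), subject-level splits,
  cross-site and few-shot protocols, accuracy / rank ROC-AUC / Brier score.
* **factor_stats** — matched-pair factor comparisons with subject-level
  sign-flip randomization tests (exact enumeration for ≤ 12 subjects, 5000
  permutations otherwise) and Benjamini–Hochberg FDR within factor.
* **stability** — site-stratified 80% subsampling, Haufe forward-model
  activation patterns via the spectral shortcut `a_pca = λ ⊙ w_pca`, and
  stable-edge selection (sign consistency ≥ 80% and repeated top-k ranking)
  with network-pair aggregation.

## Worked example

```bash
python analysis/01_simulate.py --seed 1   # write the synthetic study
python analysis/06_stability.py --seed 1  # stable-edge biomarkers
```

prints

```
5 stable edges out of 190 (top-k = 6, 100 iterations)
planted-edge recovery: precision 1.00, recall 1.00
```

meaning the stability procedure selected five edges whose activation sign
was preserved in ≥ 80% of the 100 subsamples and which repeatedly ranked in
the top ~3% by |activation| — exactly the five covariance-differential
edges the generator planted, with no false positives. The quality scripts
tell the same story from the other direction:

```
$ python analysis/03_qc_reliability.py --seed 1
QC-FC (lower = less residual motion): {'no_denoise': 0.5407, 'hmp24': 0.3972, 'oracle': 0.2387}
mean within-AROMA-family similarity 0.912 vs across families 0.710
mean edge ICC(3,1) on glasso FC: unmasked 0.345, masked to top 10 edges 0.474
```

QC-FC falls as denoising removes more of the injected nuisance structure,
FC vectors cluster by denoising family, and masking near-zero edges lifts
the mean reliability of the sparse estimator. Scripts `04` and `05` run the
classification grid and the sign-flip factor comparisons on its Brier
scores.

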