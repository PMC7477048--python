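# Methods

This note documents the models and procedures implemented in `petfactor`,
the parameter choices that matter, what the synthetic data do and do not
emulate, and the numerical details a user reproducing or extending the
pipeline should know.

## Delineation and first-order metrics

SUV is body-weight-normalized uptake (unitless); all geometry is in
physical millimetres via the voxel spacing carried by `PETVolume`.

**SUVpeak** is the maximum, over candidate centres inside the search
region, of the mean SUV in a 1-mL sphere (radius
r = (3·1000/4π)^{1/3} ≈ 6.204 mm). Sphere membership is decided by
voxel-centre distance; near the grid edge the mean runs over the in-grid
part of the sphere. The map of sphere means is computed once by
convolution, so the search is O(grid).

**Delineation** realizes the background-adapted 50% isocontour as

    T = bg + 0.5 · (SUVpeak − bg)

with the mask the largest 26-connected supra-threshold component containing
the seed. Because SUVpeak depends on the mask and vice versa, the pair is
iterated to a fixed point (cap 10 rounds; a warning and the last mask on
non-convergence — in practice the fixed point is reached in 2–3 rounds).
When no background estimate is supplied it is taken as the mean SUV in a
3-voxel-thick shell starting 2 voxels outside the current mask. Both the
connectivity rule and the shell are conventions, not physics; they are
exposed as parameters.

**Volume filter.** Lesions under 4.2 mL are rejected (three times the
6.75-mm FWHM system resolution) to limit partial-volume bias. At 4-mm
isotropic voxels this is the 65/66-voxel boundary.

TLG is always computed as SUVmean × MATV, never stored separately, so the
identity holds exactly by construction.

## Radiomic features

Discretization uses a fixed bin size (default 0.25 SUV) anchored at zero:
`level(x) = floor(x / w) + 1`. Fixed-width, zero-anchored bins are the
appropriate choice for a calibrated absolute scale like SUV, and make
grey-level differences comparable across lesions.

Families and conventions:

* **Morphology** — voxel volume; mesh volume/surface from marching cubes on
  the mask after 1-voxel Gaussian anti-aliasing (meshing the raw binary
  mask leaves a faceted staircase surface whose area does *not* converge to
  the smooth value under refinement; with anti-aliasing a digital ball's
  sphericity converges to 1). Axis lengths are 4·√eigenvalue of the
  voxel-centre coordinate covariance; elongation and flatness are ratios of
  those axes.
* **Intensity** — statistics on raw SUVs (population variance), histogram
  features on the discretized levels; histogram gradients are the first
  differences of the level counts; the intensity-volume-histogram feature
  `volume_fraction_diff` is V10 − V90, the volume-fraction spread between
  the 10% and 90% intensity fractions.
* **Moran's I** — inverse-Euclidean-distance weights over voxel centres;
  masks above 2000 voxels are uniformly subsampled with a seeded generator
  (the statistic stays unbiased; the cap bounds the O(n²) cost).
* **Texture matrices** — GLCM and GLRLM over the 13 unique directions at
  Chebyshev distance 1, features averaged over directions; GLSZM/GLDZM
  zones are 26-connected equal-level components; the GLDZM distance is the
  Chebyshev distance to the nearest non-mask voxel with the ROI edge at
  distance 1; NGTDM uses the 26-neighbourhood mean (voxels with no in-mask
  neighbour are excluded); NGLDM uses coarseness parameter α = 0 with the
  dependence count including the centre voxel (range 1..27).

Degenerate features (e.g. NGTDM contrast of a single-level lesion, CoV at
zero mean) are returned as NaN and flagged, not silently zeroed. "Inversed"
feature variants named in factor interpretations are loading-sign
phenomena, not separate features, and are intentionally not duplicated.

Every texture/intensity/axis feature is verified against an independently
coded brute-force implementation (plain loops from the definitions) to a
relative 1e-10 on seeded random lesions; this dual-implementation check is
the backbone of the test suite.

## Factor compression

1. **Redundancy filter.** Pairs with |r| ≥ 0.95 define a graph; the removal
   set is a minimum vertex cover — exact branch-and-bound per connected
   component up to 25 nodes, greedy max-degree beyond (flagged). Ties break
   toward removing the feature with the higher mean |r|, then
   lexicographically, so runs are deterministic. Constant columns are
   dropped first with a log entry.
2. **Ridge-regularized correlation.** `R_λ = (1−λ) R + λ I`, λ on a
   50-point log grid in [1e-4, 1], selected by 5-fold cross-validated
   held-out Gaussian log-likelihood (folds from a seeded shuffle;
   singular candidates skipped). The convex form keeps a unit diagonal and
   guarantees eigenvalues ≥ λ, hence positive definiteness even at p > n.
3. **Dimension.** Guttman's weakest lower bound: the number of eigenvalues
   of `R_reg` strictly greater than 1, with an optional cap. Note that the
   eigenvalues of the shrunk matrix are `(1−λ)e + λ`, so this count is
   invariant to λ: shrinkage conditions the matrix but cannot denoise the
   eigenvalue count. At p ≈ n, sampling noise lifts extra eigenvalues above
   1 (the bulk edge scales like ψ_max(1+√(p/n))²), so the bound tends to
   overcount by a few; the surplus factors are near-null and barely affect
   loading recovery (measured Tucker congruence ≈ 0.98 at n=103, p≈124,
   k=8). Parallel-analysis-style corrections are deliberately out of scope.
4. **ML factor analysis.** Eigen-based conditional maximization: given Ψ,
   Λ = Ψ^{1/2} V_k (Γ_k − I)^{1/2} from the leading eigenpairs of
   Ψ^{-1/2} R Ψ^{-1/2}; Ψ updated from diag(R − ΛΛᵀ). Convergence when the
   largest parameter change falls below 1e-6 (default cap 500 iterations;
   the pipeline allows 10 000 because Heywood-adjacent solutions converge
   slowly). Uniquenesses are floored at 0.005 and flagged (Heywood cases).
5. **Rotation.** Varimax (SVD-based iteration); communalities are invariant
   to 1e-10. Columns are ordered by explained variance and signed so each
   column's largest-|loading| entry is positive, making solutions
   comparable across runs.
6. **Scores.** Regression (Thomson) scores `F = X R_reg^{-1} Λ`. The score
   weights, z-score parameters and retained-feature list are stored so a
   validation cohort is always scored with training-frozen transforms
   ("apply" mode); re-running the whole pipeline on the validation cohort
   ("refit" mode) is also supported for structure-replication checks.

## Survival modelling and risk

Cox fits use lifelines (Efron tie handling, Breslow baseline cumulative
hazard; the baseline corresponds to a training-covariate-mean patient, so
linear predictors are mean-centred throughout). Multivariable models are
built by backward elimination with retention at p ≤ 0.157 after a
univariable screen at the same threshold; both the screen-then-combine and
the all-in strategies are available. Note the arithmetic consequence of the
threshold: a pure-noise covariate has a uniform p-value, so it is dropped
with probability 1 − 0.157 ≈ 84%, not more.

Validation metrics: Harrell's C over comparable pairs (the earlier subject
experienced the event; tied scores count one half) with a pairwise
U-statistic SE; incident/dynamic time-dependent ROC AUC (cases fail at t,
controls survive beyond t) summarized as a weighted mean with weights
(cases × controls)/G(t⁻)², G the Kaplan–Meier censoring survival (IPCW);
event-stratified k-fold cross-validation repeating the full
selection-and-fit pipeline per fold; and likelihood-ratio χ² comparison of
nested models.

**Risk calculator.** Absolute 2-year risk
`1 − exp(−H₀(24))^{exp(lp)}` with H₀ the Breslow baseline cumulative hazard
at 24 months and lp the mean-centred linear predictor. Strata are low
(< 33%), medium (33–66%) and high (≥ 66%) absolute risk — boundary values
33% and 66% fall upward, matching the printed interval convention — with a
cohort-tertile mode as an alternative. The exported calculator table
(coefficient, training mean per predictor, baseline 24-month survival)
round-trips to the computed risk exactly.

## Synthetic data: what it emulates, what it does not

* **Phantoms** mirror the acquisition scale of clinical FDG-PET: 4-mm
  isotropic voxels and a 6.75-mm FWHM point-spread function, implemented as
  a separable Gaussian with σ = FWHM/2.355. Texture heterogeneity is a
  Gaussian random field (correlation length 8 mm by default) or a
  two-compartment necrotic core, chosen because necrosis and uptake
  heterogeneity are the tissue interpretations usually attached to
  prognostic PET factors. Noise is additive Gaussian (default SD 0.1 SUV).
  Not emulated: correlated reconstruction noise, respiratory motion,
  scanner-specific harmonization — so passing tests demonstrate pipeline
  correctness, not clinical transportability.
* **Feature tables** follow the orthogonal common-factor model with
  communality + uniqueness = 1 per feature and appended clone columns at a
  target correlation (default 0.99). Gaussianity is a stand-in; real
  radiomic features are often skewed.
* **Outcomes** are proportional-hazards event times (exponential baseline
  by default, Weibull optional — the minimal model consistent with the Cox
  analysis), independent exponential censoring tuned to a target fraction,
  and an administrative cutoff at the 24-month horizon.
* **The end-to-end study** couples the three: per-patient latent drivers
  (lesion size, heterogeneity, HPV status) shape both the phantom and the
  hazards (e.g. recurrence log-hazards 0.7·size + 0.5·heterogeneity −
  0.8·HPV; baselines tuned to event fractions of roughly 26%/10%/36% within
  24 months, the scale of a chemoradiotherapy cohort). Cohort sizes default
  to 103 training + 71 validation. Clinical covariate frequencies follow a
  locally advanced HNSCC population (T2–T4, mostly N2, ~38% HPV-positive,
  median ~23 pack-years).

## Numerical choices and problem sizes

* All randomness flows from explicit seeds (`numpy` Generators /
  SeedSequence spawning); identical seeds give bit-identical outputs,
  including manifest checksums.
* The test suite runs the heavy simulations at the smallest sizes at which
  the checked properties are stable: 20 seeded 5×5×5 lesions for oracle
  equivalence, 50 seeds at n=103/p≈124 for factor recovery, 200 replicates
  at n=500 for Cox calibration, 100 simulations for the stratification
  power check, and one full 103+71 end-to-end study (about a minute on one
  core in total).
* Degenerate inputs: empty masks, constant columns, all-censored outcomes,
  single-stratum cohorts and missing covariates raise informative errors
  rather than propagating NaNs.

## Known limitations

* The feature catalogue is a documented superset of the families the factor
  interpretations require (~100 features), not a full 400+ catalogue; no
  wavelet/filtered variants, no 2D slice-wise features, no CT features.
* The Guttman eigenvalue-count bound overestimates the factor dimension at
  p ≈ n (see above); users who need exact dimension recovery at that scale
  should cap `max_k` on substantive grounds or use a larger cohort.
* Backward elimination with p ≤ 0.157 keeps ~16% of pure-noise candidates
  by construction; it trades parsimony for applicability, and the
  cross-validated concordance is the honest performance readout.
* NIfTI is the only image format (DICOM conversion is upstream of this
  package); competing-risks analysis and multiple imputation are out of
  scope (complete-case with a logged count).
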