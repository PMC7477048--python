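# petfactor

FDG-PET radiomics with latent-factor prognostic modelling, for researchers
studying image-based outcome prediction in oncology (the motivating setting
is locally advanced head-and-neck squamous cell carcinoma treated with
chemoradiotherapy).

Radiomic feature sets are large and heavily collinear: hundreds of texture
descriptors computed from one lesion, many of them near-duplicates. Instead
of picking single "best" features — which discards the correlation structure
and invites overfitting — this package compresses the feature space into a
small number of orthogonal latent **radiomic factors** and uses those, next
to clinical and first-order PET variables, in Cox survival models and a
clinically styled 2-year risk calculator.

## What the pipeline does

1. **Delineation** — background-adapted isocontour at
   `T = bg + 0.5 (SUVpeak − bg)`, with SUVpeak the hottest 1-mL sphere mean,
   iterated to a fixed point; lesions below 4.2 mL are rejected
   (partial-volume guard at 6.75-mm FWHM resolution). First-order metrics:
   SUVmax, SUVmean, SUVpeak, MATV, TLG = SUVmean × MATV.
2. **Feature extraction** — 3D IBSI-style features with fixed 0.25-SUV bins:
   morphology, intensity statistics and histogram (including histogram
   gradients), intensity-volume histogram, Moran's I, and the GLCM, GLRLM,
   GLSZM, GLDZM, NGTDM and NGLDM texture families (13-direction averaging).
3. **Factor compression** — redundancy filtering removes a *minimum vertex
   cover* of the |r| ≥ 0.95 correlation graph; the retained features are
   z-scored and their correlation matrix shrunk toward the identity,
   `R_λ = (1−λ) R + λ I`, with λ chosen by 5-fold cross-validated Gaussian
   log-likelihood; maximum-likelihood factor analysis
   `R ≈ Λ Λᵀ + Ψ` with the dimension k set by the Guttman bound
   (eigenvalues > 1); varimax rotation; regression (Thomson) scores
   `F = X R⁻¹ Λ`.
4. **Prognostics** — Cox proportional hazards (Efron ties, Breslow baseline)
   with backward elimination at the TRIPOD-style retention rule p ≤ 0.157;
   Harrell's concordance with a pairwise SE, incident/dynamic time-dependent
   ROC AUC, stratified 5-fold cross-validation, likelihood-ratio model
   comparison.
5. **Risk stratification** — absolute 2-year risk
   `1 − S₀(24)^exp(lp)` from the training-mean-centred linear predictor,
   three tiers at 33% / 66%, Kaplan–Meier + log-rank verification, and an
   exportable fill-in calculator table.

A first-class synthetic-data module generates every input with known ground
truth: blurred, noisy lesion phantoms (4-mm voxels, 6.75-mm FWHM PSF,
Gaussian-random-field or necrotic-core texture), feature tables with a known
factor structure plus redundant clone columns, and proportional-hazards
outcomes with right censoring.

## Worked example

Compressing a table with a known 4-factor structure and 6 near-duplicate
columns (`python examples/03_factor_compression.py`):

```
table: 200 patients x 46 features (6 redundant clones)
retained 40 features (removed 6)
ridge penalty lambda = 0.0869
factors k = 4, explained covariation = 69.4%
Tucker congruence with the generating loadings: mean 0.997 (per factor [0.996 0.998 0.997 0.997])
```

The filter removed exactly the 6 clones, the Guttman bound found the true
4 factors, and the rotated loadings match the generating structure almost
perfectly (congruence 1 = identical up to order/sign).

Fitting a survival model and the risk calculator
(`python examples/04_survival_and_risk.py`):

```
retained predictors: ['marker'] (dropped: ['noise'])
beta = {'marker': 1.162}, concordance = 0.734 (SE 0.019)
2-year risk: mean 0.50, strata {'medium': 148, 'low': 131, 'high': 121}
log-rank across strata: chi2 = 131.4, p = 2.90e-29
24-month KM survival by stratum: low=0.84, medium=0.46, high=0.18
```

Backward elimination kept the true marker (β̂ = 1.16 vs true 1.2) and
dropped the noise covariate; the three risk tiers separate the
Kaplan–Meier curves in the stated order.

The other examples cover phantom simulation + delineation (`01`), feature
extraction (`02`) and the full end-to-end study (`05`). A thin CLI mirrors
the stages: `petfactor simulate|segment|extract|factorize|fit|run-all`.

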