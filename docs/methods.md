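# Methods

`spectrop` estimates rice leaf phosphorus concentration (LPC, mg g⁻¹) from
leaf reflectance spectra (350–2500 nm at 1 nm, 2151 channels) through three
feature routes — exhaustively optimized two-band spectral indices, continuous
wavelet features, and the raw full-band spectrum — compared across five
regression algorithms. This note documents the models, the numerical
choices, and what the synthetic study conditions do and do not emulate.

## Two-band index optimization

For every ordered band pair (λ₁, λ₂) three index formulations are scored
against LPC:

- RSI = R₁/R₂ (ratio),
- DSI = R₁ − R₂ (difference),
- NDSI = (R₁ − R₂)/(R₁ + R₂) (normalized difference).

The score is the squared Pearson correlation between index and trait, which
is identical to the R² of the univariate ordinary-least-squares fit but far
cheaper at the full 3 × 2151² ≈ 13.9 M pair scan. The DSI map is computed
in closed form from the band covariance matrix (one Gram-matrix product);
RSI and NDSI, nonlinear in the band values, are computed one λ₁ row at a
time with vectorized column statistics. A `step` stride subsamples the band
grid for quick looks.

Undefined cells carry NaN and never rank: the diagonal, pairs with a
near-zero denominator (|·| ≤ 1e−12) for any sample, and pairs whose index
is numerically constant. "Constant" uses a *relative* variance tolerance
(variance ≤ 1e−12 of the index's mean square): below that point the
centred-moment algebra has no significant digits left, and such
essentially-constant contrasts are scientifically meaningless anyway.

Selection pools candidates across the three maps, sorts by R² (ties broken
by smaller λ₁, then λ₂, then RSI < DSI < NDSI), and greedily keeps a
candidate only if no already-kept candidate of the same index type has both
bands within `min_separation_nm` (default 10 nm) — compared in both band
orientations, since the DSI/NDSI maps are mirror-symmetric. This
de-duplication exists because the R² landscape concentrates in a few hot
spots; without it the "top 10" would be ten near-copies of one pair.

Each selected feature is calibrated by OLS (LPC = slope·index + intercept);
R² on the calibration set is the squared correlation of that fit.

## Continuous wavelet features

Each spectrum f(λ) is projected onto translated, dilated copies of a mother
wavelet: C(a, b) = Σ_λ f(λ)·s_a^(−1/2)·ψ((λ−b)/s_a)·Δλ with dyadic
dilations s_a = 2^a for scale indices a = 1..10 and Δλ = 1 nm. Choices that
the mathematics leaves open:

- **Dyadic scales.** "Scale a" means dilation 2^a nm. Dyadic ladders are
  the standard in continuous wavelet analysis of reflectance spectra and
  cover fine (2 nm) to very broad (1024 nm) absorption structure.
- **L2 normalization (1/√s).** Keeps coefficient magnitudes comparable
  across scales. Because it only rescales each scale by a positive
  constant, per-scale correlation maps and selected wavelengths are
  invariant to this choice (asserted in a test).
- **Mirror (symmetric) padding** of length 8·s_a per side — the full
  support of the sampled kernel — avoids the spurious edge responses zero
  padding would create at 350/2500 nm. The transform is evaluated by FFT
  convolution and verified against the literal defining sum in tests.
- **Wavelet set.** Mexican Hat (negative-normalized second Gaussian
  derivative, two vanishing moments) is the default; Gaussian derivatives
  of order 1–4 and a zero-mean real Morlet form a configurable screening
  set.

The scalogram of squared correlations against LPC is computed per
(scale, wavelength) cell; one feature per scale is selected (max R², ties to
the smaller wavelength) and calibrated by OLS, giving 10 wavelet features
under defaults.

## Model harness

Four feature sources — OR (2151 raw bands), SIs (10), CWT (10),
SIs+CWT (20) — are each fed to five algorithms: PLSR, LASSO, random forest
(RF), RBF-kernel support-vector regression (SVM), and a back-propagation
neural network (BPANN). The data discipline: seeded uniform 70/30
calibration/validation split (456 → 319/137 under defaults); feature
selection strictly on the calibration set; seeded 10-fold cross-validation
on the calibration table; held-out validation metrics.

"Default settings" of any particular software stack are not a reproducible
specification, so the hyperparameters are explicit:

| algorithm | settings |
|---|---|
| PLSR | components chosen by inner 5-fold CV over 1..min(10, k, n−1); features standardized |
| LASSO | penalty by inner 5-fold CV over log grid 1e−4..1e1 (30 points), cyclic coordinate descent; standardized |
| RF | 500 trees, unlimited depth, √k feature subsampling, seeded; raw features |
| SVM | RBF kernel, C = 1.0, kernel width 1/(k·Var), ε = 0.1; standardized |
| BPANN | one hidden layer of 100 logistic units, Adam, ≤ 2000 epochs, seeded; standardized |

Metrics: R² = 1 − SSres/SStot (may be negative); RMSE = √(SSres/n);
AIC = 2k + n·ln(RSS/n) computed on validation predictions with k the
feature count. A variant replacing RSS by the sum of squares of predictions
about the measured mean is available behind a flag
(`aic_metric(..., printed_variant=True)`); it is not a measure of fit and
is off by default. Calibration R² is reported both as the training-set fit
(`r2_cal_fit`) and as the 10-fold CV mean (`r2_cv`), because flexible
models (RF especially) separate the two sharply and conflating them
overstates skill.

Taylor statistics use population (divide-by-n) standard deviations so the
law-of-cosines identity cRMSD² = σ_p² + σ_o² − 2σ_pσ_o·r is exact, and the
normalized form (std ratio, reference point (1, 0)).

## Synthetic study conditions

No public accession provides the measured spectra, so the package ships a
generator that emulates the study's *statistical structure*: 19 samples per
(4 treatments × 2 cultivars × 3 layers) cell = 456 samples; treatment LPC
means (1.2, 1.9, 2.5, 3.0) mg g⁻¹ with within-cell s.d. 0.35, truncated at
0.1; a layer decrement (0.15 mg g⁻¹ per step) under P0 only; no cultivar
effect. Reflectance is a deterministic green-leaf template plus four
response channels plus noise, clipped to [0.001, 0.999]:

- **Visible (anthocyanin-like) response**, acute: a Gaussian bump at
  550 nm (width 60 nm) with amplitude vis_gain·min(deficit, cap)², where
  deficit = max(0, P3-mean − LPC). Quadratic-with-saturation: pigment
  accumulation accelerates with deficiency and plateaus under severe
  deficiency.
- **Red-edge shift**, acute: the sigmoidal red-edge midpoint (718 nm,
  width 12 nm) moves toward shorter wavelengths by 6 nm per mg g⁻¹ of the
  same capped deficit.
- **NIR structural response**, chronic: a smooth Gaussian weight
  (centre 1075 nm, width 180 nm) with amplitude nir_gain·(cell-mean LPC).
  Driving this channel by the pot's chronic P status — constant within a
  treatment cell — reflects that leaf structure integrates supply over
  weeks, and makes the channel piecewise-constant ("stepped") with respect
  to the individual trait.
- **Planted signal**: reflectance at planted_pair[0] (default 1080 nm)
  gains +0.6·planted_slope·LPC and at planted_pair[1] (1070 nm) loses
  0.4·planted_slope·LPC, so the pair difference is *exactly*
  planted_slope·LPC. The pair is symmetric about the NIR response centre,
  so the NIR weights of the two bands cancel identically and the planted
  difference is the unique exactly-linear band contrast. The uneven split
  keeps single-band contrasts strictly weaker than the pair and makes
  planted_pair[0] the unambiguous finest-scale (scale-1) wavelet pick — a
  single-band perturbation is sharpest at the finest dilation, which is
  why scale 1 is the planted scale.
- **Biological jitter**: the visible/red-edge and NIR amplitudes carry
  independent multiplicative jitter (relative s.d. 0.4, truncated at 0),
  representing leaf-to-leaf variation in pigment and structure unrelated
  to P.
- **Noise**: i.i.d. Gaussian (s.d. 0.01) with heavy-tailed contamination —
  8% of samples carry 10× noise, emulating occasional measurement
  artifacts (specular reflection, leaf-clip pressure) in field
  spectroscopy.

The defaults were calibrated once, jointly, so that the generated
conditions exhibit the qualitative phenomena the pipeline is validated
against — strict group orderings of LPC and of reflectance at 550/1000 nm;
planted-pair recovery by the DSI scan at low noise (20/20 seeds at
noise s.d. 0.002); and the model-comparison pattern in which the random
forest leads every feature source while linear models are handicapped by
the saturating/stepped responses and the contamination — and then frozen.
Two design points deserve emphasis. First, exactly linear band responses
would make many band contrasts exactly linear in LPC, so no scan could
single out the planted pair; every non-planted channel therefore carries
curvature, steps, or jitter. Second, under heavy-tailed noise the band-pair
argmax is a winner's-curse statistic (the variance estimate of each pair's
residual is itself noisy), so the planted pair's margin must be structural,
not statistical — hence the 0.6/0.4 split, which keeps every single-band
competitor at ≤ 36% of the planted signal variance.

What the generator does **not** emulate: radiative transfer (no
PROSPECT-class leaf optics), water/nitrogen covariation, instrument
splice artifacts, scan-to-scan replicate structure, or growing-season
effects. Passing tests on these conditions shows the pipeline's machinery
is correct and its comparisons behave as designed; it does not certify
real-data accuracy values.

## Problem sizes and runtime

The full-resolution scan (3 × 2151² pairs, 456 samples) takes well under a
minute per index type on one CPU; the 10-scale transform of 456 spectra a
few seconds. The model-comparison study uses 20 seeded replicate datasets;
within each, index selection runs on a 5 nm band stride (the stride grid
contains the planted bands) and wavelet selection at full resolution, and
models are compared on held-out validation R² without the cross-validation
columns — the directional median comparison does not need them. The
acceptance script runs one full-resolution, cross-validated pipeline.

## Degenerate inputs and edge cases

- Prediction-only spectra (no LPC) are valid `SpectrumSet`s; every
  operation needing the trait raises rather than imputing.
- Percent reflectance (max > 1.5) is auto-rescaled with a warning;
  fractional-nanometre wavelength headers are rejected rather than
  resampled.
- Constant indices/coefficients raise in calibration and are flagged
  undefined in maps; scales with no defined scalogram cell are omitted
  with a warning.
- A constant measured trait makes R² (and Taylor statistics) undefined and
  raises; zero residual sum of squares makes AIC −∞ and raises.
- CV folds with a constant measured trait are excluded from the R² mean
  with a warning (their RMSE still counts).

## Known limitations

- The R² landscape is scored univariately; multivariate feature synergy is
  left to the downstream models by design.
- The per-scale "one feature per scale" rule can return fewer than 10
  features if a scale's scalogram is entirely undefined.
- BPANN with logistic units and a fixed epoch cap can terminate before
  convergence on large feature sets; its seeded determinism is exact, its
  skill is not guaranteed.
- AIC on 2151-feature sources is dominated by the 2k term; it is reported
  for completeness, not used for selection.
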