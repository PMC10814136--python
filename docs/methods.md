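# Methods

`spectrareg` implements a complete near-infrared hyperspectral regression
workflow for fruit internal-quality attributes — soluble solid content
(SSC, °Brix) and pH — from reflectance calibration through model
explanation. This note records the models, the synthetic study design,
and the numerical choices a user or reviewer would want to audit.

## Reflectance calibration and band accounting

Raw push-broom cubes hold digital counts. With a white-reference cube
`W` (imaged reflectance standard) and dark-reference cube `D` (closed
shutter), reflectance is `R = (I − D) / (W − D)` per pixel and band.
Dead pixels (`W == D`) are mapped to 0 and counted in a log warning
rather than propagating NaN into region means; values above
`clip_max = 1.5` (specular highlights) are clipped, since unbounded
outliers destabilise scatter correction downstream.

The instrument grid is 224 bands over 900–1700 nm. The short-wavelength
edge of InGaAs line-scan cameras is noisy, so the first 15 bands are
dropped by default, leaving 209 bands — the sequence length every
downstream model is sized for. Cropping is count-based rather than
wavelength-threshold-based so that the band count consumed by the models
is exact by construction.

## Region extraction and spectra

Fruit regions are segmented by thresholding a single high-contrast band
(default 1100 nm at reflectance 0.25 — fruit is bright, the platform
dark), labelling connected components, discarding specks below
`min_area`, and ordering components row-major by centroid to match the
physical 3×5 platform layout. Each sample's spectrum is the arithmetic
mean over its region's pixels.

## Multiplicative scatter correction (MSC)

Each spectrum `x` is regressed on a reference spectrum `r` (by default
the set mean): `x ≈ a + b·r`, and corrected as `(x − a)/b`. This removes
per-sample multiplicative and additive scatter. Two properties worth
knowing:

- MSC needs across-wavelength structure in the reference to identify
  `b`; on a hypothetical flat reference the slope would be determined
  entirely by the analyte signal and MSC would remove the chemistry along
  with the scatter.
- Any component of the analyte signal whose spectral shape projects onto
  the span of `{1, r}` is absorbed into `(a, b)` and lost. This drove a
  generator design decision (below).

The MSC reference is computed from the full retained sample set before
splitting, matching the processing order of typical campaigns
(pre-processing precedes partitioning). This is mildly
leakage-relevant: the reference sees spectra that later land in the
prediction set. The leaked quantity is a single mean spectrum and does
not involve the targets.

Outlier screening applies Tukey fences (quartiles ± 1.5·IQR, linear
interpolation) to each target variable; a sample outside the fences for
either SSC or pH is removed.

## Screened 3:1:1 split

Samples are split calibration : validation : prediction = 3:1:1 with
`floor(N/5)` in each holdout part and the remainder in calibration
(357 → 215/71/71). Because an unlucky random split can make any model
look overfit, `n_trials` candidate splits are drawn from independent
seeded streams and each is probed with PLSR (component count by 5-fold
cross-validated grid search over 1–21 on the calibration part). A
split's score is `max(R²_C − R²_V, R²_C − R²_P, 0)`, maximised over the
two targets; the minimum-score split wins, ties to the lowest trial
index. The procedure is deterministic in `(seed, n_trials)` and any
single trial can be recomputed independently because trial `k` uses
`default_rng([seed, k])`.

## Models

Seven calibration models share one interface:

- **PLSR** (scikit-learn): components searched over 1–21 by
  cross-validated grid search on calibration only.
- **SVR** (scikit-learn): linear / polynomial (degree 3) / Gaussian
  kernels, `gamma` log-spaced over [1e−4, 1e5],
  `C ∈ {0.1, 1, 10, 100}`, 5-fold CV. Inputs are standardised in the
  pipeline and the target z-scored so the default ε-tube is meaningful
  for both °Brix and pH scales.
- **CNN**: two same-padded 1-D convolutions (1→128→256 channels, kernel
  3, ReLU), flatten, fully connected layer, dropout 0.3, scalar head;
  learning rate 0.0005.
- **LSTM**: linear lift of the 209-band spectrum to 1024 dimensions,
  consumed as a single step of a one-way LSTM with hidden size 1024.
- **CNN-LSTM**: convolutions 1→128→256→512 (kernel 3), the 512-wide band
  sequence fed through a one-way LSTM with hidden size 256; final state
  to a scalar head.
- **Transformer**: each band is one token, lifted from width 1 to
  d_model = 256, plus sinusoidal position codes; six encoder layers.
- **CNN-Transformer** (flagship): the two-conv front-end (1→128→256,
  same padding so the token count stays 209) produces 256-wide tokens;
  position codes are added and six encoder layers (4 heads,
  d_k = d_q = d_v = 64, position-wise feed-forward 256→1024→256, Add &
  Norm after both sublayers) refine the sequence; mean-pooling over the
  209 positions feeds a linear head. Learning rate 0.0008. The
  front-end convolutions are bias-free: with centred inputs the feature
  map is then proportional to spectral deviations, whereas bias terms
  add a position-independent pedestal that floods Grad-CAM profiles
  (whether rectification happens to remove the pedestal is a sign
  coin-flip per initialisation). The Transformer has ample bias
  capacity downstream, and predictive performance is unaffected.

The deep models run on the package's own numpy reverse-mode autodiff
engine (`spectrareg.nn`): conv1d via im2col, fused softmax/layer-norm
primitives, AdamW. Gradients are verified against central differences in
the test suite, and all grads are retained on intermediate tensors,
which is what Grad-CAM consumes.

### Training protocol

MSE loss, AdamW (decoupled weight decay 0.01), batch size 10.
Two stabilisers are applied that matter at a fixed base learning rate of
0.0008 on a six-layer post-LN encoder trained from scratch: a linear
learning-rate warmup over the first 50 optimiser steps and global
gradient-norm clipping at 1.0. Without them the encoder reliably stalls
at the predict-the-mean plateau; with them it converges within a handful
of epochs on the synthetic campaign. Early stopping monitors validation
RMSE with configurable patience, and the parameter state with the best
validation RMSE is restored.

Inputs to deep models are centred per band and scaled by one global
standard deviation (calibration statistics only). Per-band z-scoring was
deliberately rejected: it whitens away the amplitude contrast between
analyte-informative bands and the rest of the spectrum, and that
contrast is exactly what the convolutional feature maps — and therefore
Grad-CAM attribution — rely on. Targets are z-scored with calibration
statistics and predictions mapped back.

Default problem sizes for the acceptance runs: 357 samples, 209 bands,
8 training epochs. The convergence margin at 8 epochs is documented by
the training histories the tests produce; the budget is a package
choice sized for a single CPU.

## Evaluation

R² is the coefficient of determination `1 − Σ(ŷ−y)²/Σ(y−ȳ)²` (not
squared Pearson correlation). RPD divides the standard deviation of the
reference values (n−1 denominator) by prediction RMSE; the identity
`RPD · RMSE = SD(y)` holds exactly and is tested. Reliability classes:
RPD < 1.4 unreliable, 1.4–2.0 (inclusive) reliable, > 2.0 high — the
boundaries are assigned to the middle class since strict inequalities
leave them undefined.

## Grad-CAM saliency

For models with a convolutional front-end, the gradient of the scalar
prediction with respect to the final conv feature map `A` (256 channels
× 209 positions) gives channel weights `α_c = mean_l ∂y/∂A[c,l]`; the
map `M[l] = Σ_c α_c A[c,l]` is rectified (negative contributions
dropped, matching the nonnegative weight curves this technique
conventionally reports) and max-normalised per sample. Profiles from a
seeded random subset (default 50 samples) are averaged, with the
across-sample variance kept as an envelope, and the mean re-normalised
to 1. Because the convolutions are same-padded, position `l` maps
directly to wavelength `l` of the cropped axis.

Models without a conv front-end (plain Transformer, LSTM) are rejected
explicitly rather than silently substituted with input-gradient maps.

`band_mass_fraction(profile, lo, hi)` quantifies localization as the
fraction of total profile mass inside a wavelength window; comparing it
with the window's share of bands gives an enrichment ratio.

## Synthetic study design

No public reference dataset exists for this task, so the generator
defines the study conditions. Targets follow the campaign statistics of
a 357-fruit study: SSC ~ N(6.90, 1.41²) truncated to [4.20, 10.20]
°Brix; pH ~ N(4.20, 0.20²) truncated to [3.77, 4.78]. Truncated normals
are sampled by rejection (exact; the truncations are mild).

Spectra follow a Beer–Lambert-style forward model. The baseline is the
reflectance of the *average-composition* fruit: a smooth declining
continuum (0.62 → 0.44 over 900–1700 nm with mild curvature near
1150 nm). Gaussian absorption bands encode composition *deviations*:

    A(λ) = Σ_bands [coeff_ssc·(SSC − 6.90) + coeff_ph·(pH − 4.20)] · exp(−(λ−c)²/2σ²)
    clean(λ) = baseline(λ) · 10^(−A(λ))
    observed  = offset + slope·clean + ε,   ε ~ N(0, 0.005²)

with slope ~ U(0.7, 1.3) and offset ~ U(−0.05, 0.05) per sample. The
deviation form is deliberate: if the mean absorption dip were present in
every spectrum it would also sit in the MSC reference, making dip-depth
variation nearly collinear with the multiplicative scatter slope — MSC
would then remove the analyte signal along with the scatter (measured:
the informative-band excess variance essentially vanished under the
uncentered form). Modelling the baseline as the average fruit and bands
as deviations keeps scatter and chemistry identifiable, which is also
why the baseline carries no feature at the band positions.

Default informative windows mirror the known chemistry-bearing regions:
the SSC signal lives inside 1380–1650 nm and the pH signal inside
945–1280 nm. Each analyte's signature is a *compensated triplet*: a
centre absorption band with opposite-sign flanking bands (SSC: 1420/σ35
at −0.01494, 1500/σ40 at +0.03, 1580/σ35 at −0.01942 absorbance per
°Brix; pH: 1000/σ30 at +0.2, 1100/σ35 at −0.15405, 1200/σ30 at
−0.00934 per pH unit). Physically this reads as the analyte's
absorption displacing a neighbouring absorber (more sugar, less free
water); numerically the coefficients are chosen in the nullspace of the
projection onto span{1, baseline} over the retained 209 bands. That
orthogonality matters: a single-sign dip has a component along the MSC
reference, and the per-sample affine fit converts exactly that
component into a spectrum-wide affine ghost that is (a) perfectly
correlated with the analyte and (b) largest at the spectral edges —
models then predict from the edge ghost and attribution honestly
highlights the edges rather than the chemistry. With the compensated
triplets the signal survives MSC fully localised: the in-window
standard deviation after correction is 3–4× the out-of-window noise
floor and the spectrum edges stay at the floor.

`ssc_analog_bands()` / `ph_analog_bands()` give single-analyte variants
in which the named window is the *only* structured signal; these are
what the saliency localization checks train on, so the expected answer
is unambiguous. `default_bands()` combines both triplets for two-target
campaigns.

Scene cubes paint each sample as a filled disk (uniform spectrum, no
within-disk texture) on a uniform dark background in a 3×5 grid with
slight seeded jitter and non-overlap by construction.

What the generator does **not** emulate: sensor point-spread, specular
highlights, curvature shading across the fruit surface, wavelength-
correlated noise, and instrument drift between scans. Consequently,
passing tests demonstrate that the algorithms are implemented correctly
and behave as designed under known physics — not that the models reach
any particular accuracy on real fruit.

## Degenerate inputs and tie-breaks

- `generate_targets` with `sd = 0` returns the mean (which must lie in
  the interval).
- MSC raises a `DegenerateSampleError` naming samples whose fitted slope
  magnitude is below 1e−10 (e.g. flat spectra).
- `rpd` returns +inf with a warning when RMSE is exactly 0; `r_squared`
  refuses constant reference vectors.
- Segmentation returns an empty list (with a warning) when no component
  passes the area filter.
- Split screening ties break to the lowest trial index.
- Training raises `DivergedTrainingError` with the epoch at the first
  non-finite loss.

## Known limitations

- The numpy training stack is single-machine and CPU-bound; the
  architecture is faithful but wall-clock is far from GPU frameworks.
- Grad-CAM's channel-mean weighting discards position-specific gradient
  information; on data where several spectral regions carry comparable
  activation amplitude, profiles blur across them. The package keeps
  the classic formula and makes localization testable through the
  single-analyte generators instead of switching to a position-preserving
  variant.
- MSC inevitably absorbs any signal component collinear with the
  reference; quantifying that absorption for a given band layout is
  possible with the generator's ground truth.
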