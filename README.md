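# spectrareg

Near-infrared hyperspectral regression for fruit internal quality.
`spectrareg` takes line-scan reflectance cubes of fruit (900–1700 nm,
224 bands) through the full chemometric workflow used to predict soluble
solid content (SSC, °Brix) and pH without cutting the fruit open:

1. **Calibration** — white/dark reference correction
   `R = (I − D)/(W − D)`, ENVI cube I/O, noisy-edge band cropping
   (224 → 209 bands).
2. **Spectra extraction** — fruit segmentation on a high-contrast band,
   per-fruit mean spectra.
3. **Pre-processing** — multiplicative scatter correction (MSC), Tukey
   box-plot outlier screening, and a PLSR-screened 3:1:1
   calibration/validation/prediction split.
4. **Calibration models** — PLSR and SVR (scikit-learn, cross-validated
   grids) plus five deep models built on the package's own numpy
   autodiff stack: CNN, LSTM, CNN-LSTM, Transformer encoder, and the
   flagship **CNN-Transformer** (two same-padded 1-D convolutions
   1→128→256 produce 256-wide tokens for the 209 bands; sinusoidal
   positional encoding; six encoder layers with 4-head scaled
   dot-product attention, `softmax(QKᵀ/√d_k)V`, d_k = 64, feed-forward
   256→1024→256; mean-pool; linear head; trained with AdamW, MSE loss,
   lr 0.0008, batch 10, early stopping).
5. **Evaluation** — R² (coefficient of determination), RMSE, and
   RPD = SD(y)/RMSEP with the conventional reliability bands
   (< 1.4 unreliable, 1.4–2.0 reliable, > 2.0 high).
6. **Explanation** — Grad-CAM on the final conv feature map gives a
   per-wavelength importance profile (mean over 50 random samples with a
   variance envelope), and `band_mass_fraction` quantifies how much
   saliency falls in a wavelength window.

Because public reference datasets for this task are not deposited, the
package ships a first-class synthetic generator
(`spectrareg.synthetic`): truncated-normal targets matching a 357-fruit
campaign (SSC 6.90 ± 1.41 °Brix on [4.20, 10.20]; pH 4.20 ± 0.20 on
[3.77, 4.78]), Beer–Lambert spectra with Gaussian absorption bands at
known wavelengths (SSC signal inside 1380–1650 nm, pH inside
945–1280 nm), per-sample multiplicative/additive scatter, and full
scene cubes with pixel-true masks. Every stage of the pipeline is
testable against this ground truth. See `docs/methods.md` for the
forward model and all design decisions.

## Worked example

```python
import numpy as np
import spectrareg as sr
from spectrareg.models import TrainConfig, build_model, train_model
from spectrareg.saliency import aggregate_profiles, band_mass_fraction
from spectrareg.synthetic import ssc_analog_bands

# a 357-sample campaign whose only structured signal is the SSC bands
cfg = sr.SyntheticConfig(n_samples=357, bands=ssc_analog_bands(), seed=2024)
spectra, targets, truth = sr.generate_dataset(cfg)
corrected, _ = sr.msc_fit_apply(sr.crop_bands(spectra))   # 224 -> 209 bands, MSC

perm = np.random.default_rng(7).permutation(357)          # 215 / 71 / 71
cal, val, pred = np.sort(perm[:215]), np.sort(perm[215:286]), np.sort(perm[286:])
x, y = corrected.values, targets.ssc

model = build_model("cnn_transformer", x.shape[1], seed=0)
trained = train_model(model, x[cal], y[cal], x[val], y[val],
                      TrainConfig(max_epochs=8, patience=8, seed=0),
                      kind="cnn_transformer")
print("R2_P =", round(sr.r_squared(y[pred], trained.predict(x[pred])), 3))
print("RPD  =", round(sr.rpd(y[pred], trained.predict(x[pred])), 2))

profile = aggregate_profiles(trained, x, n=50, seed=5,
                             wavelengths=corrected.wavelengths)
print("saliency mass in 1380-1650 nm =",
      round(band_mass_fraction(profile, 1380, 1650), 3))
```

On this synthetic campaign the run prints

```
R2_P = 0.987
RPD  = 8.7
saliency mass in 1380-1650 nm = 0.671
```

— a prediction-set R² near 0.99 (the generator's scatter and noise are
fully removable, so recovery is far easier than on real fruit), an RPD
deep in the "high reliability" class, and two thirds of the saliency
mass inside the window that actually carries the SSC signal (a uniform
profile would put 0.364 there — an enrichment of ~1.9, which is the
property the test suite asserts).

The same workflow is scriptable from the shell:

```bash
spectrareg simulate --n 357 --out data/ --seed 7
spectrareg preprocess --spectra data/spectra.csv --out data/pre.csv
spectrareg split --spectra data/pre.csv --out data/split.json --trials 10 --seed 7
spectrareg train --spectra data/pre.csv --split data/split.json \
                 --model cnn_transformer --target ssc --out data/metrics.json
spectrareg explain --spectra data/pre.csv --split data/split.json \
                   --target ssc --out data/saliency.csv
```

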