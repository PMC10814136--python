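"""From calibrated cubes to model-ready spectra: segmentation, ROI means,
multiplicative scatter correction, outlier screening, and the 3:1:1 split.

The modeling currency throughout the package is the ``SpectraMatrix``:
one mean reflectance spectrum per fruit, tied to a wavelength axis.  MSC
removes per-sample scattering distortions by regressing each spectrum on
a reference spectrum (by default the set mean) and inverting the fitted
affine map.  The calibration/validation/prediction split is screened with
a fast PLSR probe so an unlucky random partition cannot make a model look
overfit (or spuriously good).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import GridSearchCV

from .exceptions import DegenerateSampleError, ParameterError

__all__ = [
    "SpectraMatrix",
    "TargetTable",
    "MscModel",
    "DatasetSplit",
    "segment_samples",
    "mean_spectra",
    "msc_fit_apply",
    "boxplot_outlier_filter",
    "partition_screened",
    "save_spectra_csv",
    "load_spectra_csv",
]

logger = logging.getLogger(__name__)


@dataclass
class SpectraMatrix:
    """N x B reflectance values with wavelength axis and sample labels."""

    values: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("values must be N x B")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("spectra must be finite everywhere")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.values.shape[1]:
            raise ParameterError("wavelengths must be length-B")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ParameterError("sample_ids must be length-N")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def subset(self, idx) -> "SpectraMatrix":
        idx = np.asarray(idx)
        return SpectraMatrix(self.values[idx], self.wavelengths.copy(),
                             [self.sample_ids[i] for i in idx])


@dataclass
class TargetTable:
    """Per-sample SSC (°Brix) and pH reference values."""

    ssc: np.ndarray
    ph: np.ndarray
    sample_ids: list[str]

    def __post_init__(self):
        self.ssc = np.asarray(self.ssc, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        if self.ssc.shape != self.ph.shape or self.ssc.ndim != 1:
            raise ParameterError("ssc and ph must be 1-D vectors of equal length")
        if len(self.sample_ids) != self.ssc.size:
            raise ParameterError("sample_ids must match target length")
        if np.any(self.ssc <= 0):
            raise ParameterError("SSC values must be positive")
        if np.any((self.ph <= 0) | (self.ph >= 14)):
            raise ParameterError("pH values must lie in (0, 14)")

    def column(self, name: str) -> np.ndarray:
        if name not in ("ssc", "ph"):
            raise ParameterError("target name must be 'ssc' or 'ph'")
        return getattr(self, name)

    def subset(self, idx) -> "TargetTable":
        idx = np.asarray(idx)
        return TargetTable(self.ssc[idx], self.ph[idx], [self.sample_ids[i] for i in idx])


@dataclass
class MscModel:
    """Reference spectrum plus the fitted per-sample affine coefficients."""

    reference: np.ndarray
    intercept: np.ndarray
    slope: np.ndarray


@dataclass
class DatasetSplit:
    """Disjoint calibration/validation/prediction index sets (3:1:1)."""

    cal_idx: np.ndarray
    val_idx: np.ndarray
    pred_idx: np.ndarray
    seed: int
    screening_score: float = float("nan")

    def __post_init__(self):
        self.cal_idx = np.asarray(self.cal_idx, dtype=int)
        self.val_idx = np.asarray(self.val_idx, dtype=int)
        self.pred_idx = np.asarray(self.pred_idx, dtype=int)
        parts = [set(self.cal_idx), set(self.val_idx), set(self.pred_idx)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ParameterError("split parts must be pairwise disjoint")

    def to_json(self, path, sample_ids=None):
        def ids(idx):
            return [sample_ids[i] for i in idx] if sample_ids else idx.tolist()
        payload = {
            "cal": ids(self.cal_idx), "val": ids(self.val_idx), "pred": ids(self.pred_idx),
            "seed": self.seed, "screening_score": self.screening_score,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Segmentation and spectra extraction
# ---------------------------------------------------------------------------

def segment_samples(cube, band_nm: float = 1100.0, threshold: float = 0.25,
                    min_area: int = 20) -> list[np.ndarray]:
    """Locate fruit regions in a reflectance cube.

    Thresholds a single high-contrast band, labels connected components,
    drops specks below ``min_area`` pixels, and orders the surviving
    regions row-major (top-to-bottom, then left-to-right by centroid) to
    match the physical platform layout.  Returns boolean masks.
    """
    wl = cube.wavelengths
    if not wl[0] <= band_nm <= wl[-1]:
        raise ParameterError(f"band {band_nm} nm outside the wavelength axis")
    band_idx = int(np.argmin(np.abs(wl - band_nm)))
    binary = cube.data[:, :, band_idx] > threshold
    labels = measure.label(binary, connectivity=2)
    regions = [r for r in measure.regionprops(labels) if r.area >= min_area]
    if not regions:
        logger.warning("segment_samples: no component with area >= %d", min_area)
        return []
    # group regions into rows, then sort each row left-to-right
    regions.sort(key=lambda r: r.centroid[0])
    heights = [r.bbox[2] - r.bbox[0] for r in regions]
    row_tol = 0.5 * float(np.median(heights))
    rows: list[list] = [[regions[0]]]
    for r in regions[1:]:
        if r.centroid[0] - np.mean([q.centroid[0] for q in rows[-1]]) > row_tol:
            rows.append([r])
        else:
            rows[-1].append(r)
    ordered = [r for row in rows for r in sorted(row, key=lambda q: q.centroid[1])]
    return [labels == r.label for r in ordered]


def mean_spectra(cube, masks) -> SpectraMatrix:
    """Mean spectrum over each ROI mask; rows follow mask order."""
    if len(masks) == 0:
        raise ParameterError("masks must be non-empty")
    height, width, _ = cube.data.shape
    out = np.empty((len(masks), cube.wavelengths.size))
    for k, mask in enumerate(masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (height, width):
            raise ParameterError(f"mask {k} does not match cube spatial shape")
        if not mask.any():
            raise ParameterError(f"mask {k} is empty")
        out[k] = cube.data[mask].mean(axis=0)
    ids = [f"roi_{k:03d}" for k in range(len(masks))]
    return SpectraMatrix(values=out, wavelengths=cube.wavelengths.copy(), sample_ids=ids)


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def msc_fit_apply(x: SpectraMatrix, reference: np.ndarray | None = None,
                  min_slope: float = 1e-10):
    """Multiplicative scatter correction.

    Each spectrum is regressed on the reference (ordinary least squares,
    ``spectrum ≈ a + b * reference``) and corrected as ``(spectrum - a) / b``.
    When ``reference`` is omitted it is the column mean of ``x`` (requires
    N >= 2).  Returns ``(corrected SpectraMatrix, MscModel)``.
    """
    values = x.values
    if reference is None:
        if values.shape[0] < 2:
            raise ParameterError("default reference needs at least 2 spectra")
        reference = values.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (values.shape[1],):
        raise ParameterError("reference must be a length-B vector")
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise ParameterError("reference spectrum is constant; MSC undefined")
    row_means = values.mean(axis=1)
    slope = (values - row_means[:, None]) @ ref_c / denom
    bad = np.abs(slope) < min_slope
    if bad.any():
        raise DegenerateSampleError([x.sample_ids[i] for i in np.flatnonzero(bad)])
    intercept = row_means - slope * reference.mean()
    corrected = (values - intercept[:, None]) / slope[:, None]
    model = MscModel(reference=reference.copy(), intercept=intercept, slope=slope)
    out = SpectraMatrix(values=corrected, wavelengths=x.wavelengths.copy(),
                        sample_ids=list(x.sample_ids))
    return out, model


def boxplot_outlier_filter(t: TargetTable, k: float = 1.5) -> np.ndarray:
    """Tukey-fence outlier screening on the reference values.

    For each target the fences are [Q1 - k*IQR, Q3 + k*IQR] (quartiles by
    linear interpolation); a sample is removed when either its SSC or its
    pH falls outside its fences.  Returns the retained indices.
    """
    if t.ssc.size < 4:
        raise ParameterError("need at least 4 samples for quartile fences")
    keep = np.ones(t.ssc.size, dtype=bool)
    for values in (t.ssc, t.ph):
        q1, q3 = np.percentile(values, [25, 75])
        iqr = q3 - q1
        keep &= (values >= q1 - k * iqr) & (values <= q3 + k * iqr)
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# Screened partitioning
# ---------------------------------------------------------------------------

def _split_sizes(n: int, ratio: tuple[int, int, int]) -> tuple[int, int, int]:
    unit = n // sum(ratio)
    n_val = unit * ratio[1]
    n_pred = unit * ratio[2]
    return n - n_val - n_pred, n_val, n_pred


def _plsr_probe_r2(x_part, y_part, model) -> float:
    pred = model.predict(x_part).ravel()
    ss_res = float(np.sum((pred - y_part) ** 2))
    ss_tot = float(np.sum((y_part - y_part.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def partition_screened(x: SpectraMatrix, t: TargetTable, ratio=(3, 1, 1),
                       n_trials: int = 10, seed: int = 0,
                       max_components: int = 21, cv_folds: int = 5) -> DatasetSplit:
    """Draw ``n_trials`` random 3:1:1 splits and keep the least-overfit one.

    Each candidate split is probed with PLSR (component count chosen by
    cross-validated grid search on the calibration part, grid 1..21) for
    both targets; its score is the worst calibration-to-holdout R² gap,
    ``max(R²_C - R²_V, R²_C - R²_P, 0)``, maximised over targets.  The
    minimum-score split wins (ties go to the lowest trial index), making
    the procedure deterministic in ``(seed, n_trials)``.
    """
    n = x.n_samples
    if n < 10:
        raise ParameterError("need at least 10 samples to partition")
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    n_cal, n_val, n_pred = _split_sizes(n, ratio)
    if min(n_cal, n_val, n_pred) < 1:
        raise ParameterError("a split part would be empty at this ratio")

    best = None
    for trial in range(n_trials):
        rng = np.random.default_rng([seed, trial])
        perm = rng.permutation(n)
        cal = np.sort(perm[:n_cal])
        val = np.sort(perm[n_cal:n_cal + n_val])
        pred = np.sort(perm[n_cal + n_val:])
        score = 0.0
        for target in ("ssc", "ph"):
            y = t.column(target)
            grid = GridSearchCV(
                PLSRegression(scale=False),
                {"n_components": list(range(1, min(max_components, x.n_bands, n_cal - 1) + 1))},
                cv=cv_folds, scoring="neg_mean_squared_error")
            grid.fit(x.values[cal], y[cal])
            model = grid.best_estimator_
            r2_c = _plsr_probe_r2(x.values[cal], y[cal], model)
            r2_v = _plsr_probe_r2(x.values[val], y[val], model)
            r2_p = _plsr_probe_r2(x.values[pred], y[pred], model)
            score = max(score, r2_c - r2_v, r2_c - r2_p)
        score = max(score, 0.0)
        if best is None or score < best[0]:
            best = (score, cal, val, pred)
    score, cal, val, pred = best
    return DatasetSplit(cal_idx=cal, val_idx=val, pred_idx=pred, seed=seed,
                        screening_score=float(score))


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def save_spectra_csv(path, x: SpectraMatrix, t: TargetTable | None = None):
    """Write a spectra table: sample_id, one column per wavelength, then targets."""
    cols = {f"{w:.2f}": x.values[:, j] for j, w in enumerate(x.wavelengths)}
    frame = pd.DataFrame({"sample_id": x.sample_ids, **cols})
    if t is not None:
        if list(t.sample_ids) != list(x.sample_ids):
            raise ParameterError("target and spectra sample ids differ")
        frame["ssc"] = t.ssc
        frame["ph"] = t.ph
    frame.to_csv(path, index=False)


def load_spectra_csv(path):
    """Read a spectra table written by :func:`save_spectra_csv`.

    Returns ``(SpectraMatrix, TargetTable | None)``.
    """
    frame = pd.read_csv(path)
    band_cols = [c for c in frame.columns if c not in ("sample_id", "ssc", "ph")]
    wavelengths = np.array([float(c) for c in band_cols])
    x = SpectraMatrix(values=frame[band_cols].to_numpy(float), wavelengths=wavelengths,
                      sample_ids=frame["sample_id"].astype(str).tolist())
    t = None
    if "ssc" in frame.columns and "ph" in frame.columns:
        t = TargetTable(ssc=frame["ssc"].to_numpy(float), ph=frame["ph"].to_numpy(float),
                        sample_ids=list(x.sample_ids))
    return x, t
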