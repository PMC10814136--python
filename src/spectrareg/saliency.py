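"""Grad-CAM wavelength-importance profiles for 1-D regression models.

Classic Grad-CAM, adapted to spectra: gradients of the scalar prediction
with respect to the final convolutional feature map give per-channel
importance weights; the weighted channel sum, rectified and
max-normalised, is a per-position (hence per-wavelength, thanks to
same-padded convolutions) saliency profile.  Profiles from a random
subset of samples are averaged — with an across-sample variance
envelope — to show which spectral regions the model actually uses.
Models without a convolutional front-end have no feature map to attribute
over and are rejected explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, UnsupportedModelError
from .models import TrainedModel
from .nn import Module

__all__ = [
    "SaliencyProfile",
    "gradcam_profile",
    "aggregate_profiles",
    "band_mass_fraction",
    "plot_profile",
]


@dataclass
class SaliencyProfile:
    """Per-wavelength mean Grad-CAM weight with its variance envelope."""

    wavelengths: np.ndarray
    mean_weight: np.ndarray
    variance: np.ndarray
    n_samples: int

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.mean_weight = np.asarray(self.mean_weight, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if not (self.wavelengths.shape == self.mean_weight.shape == self.variance.shape):
            raise ParameterError("profile vectors must share length")
        if np.any(self.mean_weight < 0) or np.any(self.variance < 0):
            raise ParameterError("weights and variances must be non-negative")


def _require_conv(trained: TrainedModel) -> Module:
    model = trained.model
    if not isinstance(model, Module) or not getattr(model, "has_conv", False):
        raise UnsupportedModelError(
            f"Grad-CAM needs a convolutional front-end; model kind {trained.kind!r} has none")
    return model


def _raw_profiles(trained: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Rectified, per-sample max-normalised Grad-CAM maps, one row per input row.

    Samples do not interact in any layer (attention and normalisation act
    within a sample), so a batched forward/backward yields each sample's
    own gradients; batches are kept small to bound the retained graph.
    """
    model = _require_conv(trained)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != trained.n_bands:
        raise ParameterError(f"expected N x {trained.n_bands} input")
    z = x
    if trained.x_mean is not None:
        z = (x - trained.x_mean) / trained.x_sd
    model.eval()
    cams = []
    for start in range(0, z.shape[0], 10):
        out = model(z[start:start + 10].astype(np.float32))  # (n, 1)
        for p in model.parameters():
            p.grad = None
        out.sum().backward()
        feats = model.conv_features
        a = feats.data  # (n, C, L)
        g = feats.grad
        alpha = g.mean(axis=2)  # (n, C) channel weights
        cam = np.einsum("nc,ncl->nl", alpha, a)
        np.maximum(cam, 0.0, out=cam)
        peak = cam.max(axis=1, keepdims=True)
        nonzero = peak[:, 0] > 0
        cam[nonzero] /= peak[nonzero]
        cams.append(cam.astype(float))
    return np.vstack(cams)


def gradcam_profile(trained: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Grad-CAM weight per wavelength for a single spectrum (length-B vector)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[0] != 1:
        raise ParameterError("gradcam_profile takes one spectrum; use aggregate_profiles")
    return _raw_profiles(trained, x)[0]


def aggregate_profiles(trained: TrainedModel, x: np.ndarray, n: int = 50,
                       seed: int = 0, wavelengths: np.ndarray | None = None) -> SaliencyProfile:
    """Average Grad-CAM profiles over a seeded random subset of ``n`` rows.

    The mean profile is re-normalised to a maximum of 1; the variance is
    the across-sample variance of the individual normalised profiles.
    """
    x = np.asarray(x, dtype=float)
    if n <= 0:
        raise ParameterError("n must be positive")
    if n > x.shape[0]:
        raise ParameterError(f"n={n} exceeds the {x.shape[0]} available rows")
    rng = np.random.default_rng(seed)
    idx = rng.choice(x.shape[0], size=n, replace=False)
    profiles = _raw_profiles(trained, x[idx])
    mean = profiles.mean(axis=0)
    variance = profiles.var(axis=0)
    peak = mean.max()
    if peak > 0:
        mean = mean / peak
    if wavelengths is None:
        wavelengths = trained.extra.get("wavelengths")
    if wavelengths is None:
        wavelengths = np.arange(trained.n_bands, dtype=float)
    return SaliencyProfile(wavelengths=np.asarray(wavelengths, dtype=float),
                           mean_weight=mean, variance=variance, n_samples=int(n))


def band_mass_fraction(profile: SaliencyProfile, lo_nm: float, hi_nm: float) -> float:
    """Fraction of total saliency mass inside the window [lo_nm, hi_nm]."""
    if lo_nm >= hi_nm:
        raise ParameterError("lo_nm must be < hi_nm")
    total = float(profile.mean_weight.sum())
    if total == 0:
        return 0.0
    inside = (profile.wavelengths >= lo_nm) & (profile.wavelengths <= hi_nm)
    return float(profile.mean_weight[inside].sum()) / total


def plot_profile(profile: SaliencyProfile, ax=None, label: str | None = None):
    """Plot the mean weight with a ±1 SD shaded envelope; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    sd = np.sqrt(profile.variance)
    ax.plot(profile.wavelengths, profile.mean_weight, lw=1.2, label=label)
    ax.fill_between(profile.wavelengths, np.clip(profile.mean_weight - sd, 0, None),
                    profile.mean_weight + sd, alpha=0.25)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("Grad-CAM weight")
    if label:
        ax.legend(frameon=False)
    return ax
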