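"""Synthetic NIR hyperspectral data with known ground truth.

Real reference datasets for fruit-quality chemometrics are rarely
deposited, so every downstream stage of this package (calibration,
segmentation, MSC, regression, saliency) is exercised on simulated data
whose generative process is fully known.  The forward model is
Beer-Lambert-like: each quality attribute (SSC in °Brix, pH) contributes
Gaussian absorption bands to an absorbance spectrum, which attenuates a
smooth baseline reflectance; per-sample multiplicative/additive scatter
and white noise are then applied — exactly the distortions multiplicative
scatter correction is designed to remove.

Default target statistics mimic a 357-fruit cherry-tomato campaign:
SSC ~ N(6.90, 1.41²) truncated to [4.20, 10.20] °Brix and
pH ~ N(4.20, 0.20²) truncated to [3.77, 4.78].  Default informative
windows place the SSC signal inside 1380-1650 nm and the pH signal
inside 945-1280 nm (compensated band triplets; see
:func:`ssc_analog_bands`), so wavelength-saliency localization is a
testable property with a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError, ParameterError

__all__ = [
    "ComponentBand",
    "SyntheticConfig",
    "GroundTruth",
    "default_wavelengths",
    "default_baseline",
    "default_bands",
    "ssc_analog_bands",
    "ph_analog_bands",
    "generate_targets",
    "generate_spectra",
    "generate_scene_cube",
    "generate_dataset",
]

#: Table-level defaults for the simulated campaign.
SSC_MEAN, SSC_SD, SSC_LO, SSC_HI = 6.90, 1.41, 4.20, 10.20
PH_MEAN, PH_SD, PH_LO, PH_HI = 4.20, 0.20, 3.77, 4.78
N_SAMPLES_DEFAULT = 357


def default_wavelengths(n_bands: int = 224, lo_nm: float = 900.0, hi_nm: float = 1700.0) -> np.ndarray:
    """Uniform wavelength grid of an InGaAs line-scan camera (224 bands, 900-1700 nm)."""
    return np.linspace(lo_nm, hi_nm, n_bands)


def default_baseline(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth, gently declining reflectance continuum in (0, 1).

    This is the spectrum of the *average-composition* fruit: a broad
    declining trend with mild curvature, as matte fruit skin shows in the
    NIR.  The trend is essential — multiplicative scatter correction
    identifies the per-sample slope from exactly this across-wavelength
    structure, so a flat baseline would make scatter and analyte signal
    indistinguishable.  The baseline deliberately carries no feature at
    the analyte band positions; composition-dependent absorption is added
    on top by :func:`generate_spectra`.
    """
    w = np.asarray(wavelengths, dtype=float)
    u = (w - w[0]) / (w[-1] - w[0])
    return 0.62 - 0.18 * u + 0.06 * np.exp(-((w - 1150.0) / 180.0) ** 2)


@dataclass(frozen=True)
class ComponentBand:
    """One Gaussian absorption band tied to the quality attributes.

    ``coeff_ssc``/``coeff_ph`` are absorbance depths per unit of analyte
    (per °Brix and per pH unit respectively) at the band centre.
    """

    center_nm: float
    width_nm: float
    coeff_ssc: float = 0.0
    coeff_ph: float = 0.0

    def __post_init__(self):
        if self.width_nm <= 0:
            raise ParameterError("band width_nm must be positive")


def default_bands() -> list[ComponentBand]:
    """SSC-informative bands at 1450/1550 nm; pH-informative at 1000/1200 nm."""
    return ssc_analog_bands() + ph_analog_bands()


def ssc_analog_bands() -> list[ComponentBand]:
    """Only the SSC signal (inside the 1380-1650 nm window); used when the
    spectral footprint of a single analyte must be the only structure.

    The triplet is a centre absorption band with compensating flanks
    (stronger sugar absorption displaces water absorption nearby); the
    coefficients are balanced so the net signal shape is orthogonal to
    the span of {1, baseline} over the retained 209 bands, which stops
    multiplicative scatter correction from aliasing the localized signal
    into a spectrum-wide affine ghost.
    """
    return [
        ComponentBand(1420.0, 35.0, coeff_ssc=-0.01494),
        ComponentBand(1500.0, 40.0, coeff_ssc=0.03),
        ComponentBand(1580.0, 35.0, coeff_ssc=-0.01942),
    ]


def ph_analog_bands() -> list[ComponentBand]:
    """Only the pH signal (inside the 945-1280 nm window); see
    :func:`ssc_analog_bands` for the compensated-triplet rationale."""
    return [
        ComponentBand(1000.0, 30.0, coeff_ph=0.2),
        ComponentBand(1100.0, 35.0, coeff_ph=-0.15405),
        ComponentBand(1200.0, 30.0, coeff_ph=-0.00934),
    ]


@dataclass
class SyntheticConfig:
    """Full description of the simulated acquisition.

    Defaults encode the reference study conditions: 224 bands over
    900-1700 nm, scatter slope ~ U(0.7, 1.3), offset ~ U(-0.05, 0.05)
    and additive noise sd 0.005 reflectance units.
    """

    n_samples: int = N_SAMPLES_DEFAULT
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    baseline: np.ndarray | None = None
    bands: list[ComponentBand] = field(default_factory=default_bands)
    scatter_slope_range: tuple[float, float] = (0.7, 1.3)
    scatter_offset_range: tuple[float, float] = (-0.05, 0.05)
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ParameterError("wavelengths must be a 1-D grid with >= 2 points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        lo, hi = self.scatter_slope_range
        if lo <= 0 <= hi:
            raise ParameterError("scatter_slope_range must exclude 0")
        if self.baseline is None:
            self.baseline = default_baseline(self.wavelengths)
        else:
            self.baseline = np.asarray(self.baseline, dtype=float)
            if self.baseline.shape != self.wavelengths.shape:
                raise ParameterError("baseline must match the wavelength grid")
        if np.any((self.baseline <= 0) | (self.baseline >= 1)):
            raise ParameterError("baseline reflectance must lie in (0, 1)")
        span_lo, span_hi = self.wavelengths[0], self.wavelengths[-1]
        for b in self.bands:
            if not span_lo <= b.center_nm <= span_hi:
                raise ParameterError(f"band centre {b.center_nm} nm outside the grid span")


@dataclass
class GroundTruth:
    """Everything the generator knows that a real experiment would not."""

    ssc: np.ndarray
    ph: np.ndarray
    slope: np.ndarray
    offset: np.ndarray
    clean_spectra: np.ndarray


def generate_targets(n: int, mean: float, sd: float, lo: float, hi: float,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n`` reference values from a truncated normal on [lo, hi].

    Sampling is by rejection, which is exact; with ``sd == 0`` every value
    is ``mean`` (which must then lie inside the interval).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if lo >= hi:
        raise ParameterError("lo must be < hi")
    if sd < 0:
        raise ParameterError("sd must be >= 0")
    if sd == 0:
        if not lo <= mean <= hi:
            raise ParameterError("with sd=0, mean must lie inside [lo, hi]")
        return np.full(n, float(mean))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 64))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def _absorbance(ssc: np.ndarray, ph: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    # Absorbance deviations around the average-composition fruit: the
    # baseline already contains the mean analyte absorption, so bands act
    # on (analyte - campaign mean).  Keeping the mean dip out of the
    # spectra stops MSC's per-sample slope fit from soaking up the
    # composition signal along with the scatter.
    w = config.wavelengths
    a = np.zeros((ssc.size, w.size))
    for band in config.bands:
        profile = np.exp(-((w - band.center_nm) ** 2) / (2.0 * band.width_nm ** 2))
        depth = band.coeff_ssc * (ssc - SSC_MEAN) + band.coeff_ph * (ph - PH_MEAN)
        a += depth[:, None] * profile[None, :]
    return a


def generate_spectra(ssc: np.ndarray, ph: np.ndarray, config: SyntheticConfig):
    """Simulate observed reflectance spectra for given reference values.

    Returns ``(SpectraMatrix, GroundTruth)``.  Clean reflectance is
    ``baseline * 10**(-A)`` with A the summed Gaussian-band absorbance;
    the observation adds per-sample affine scatter and white noise.
    """
    from .pipeline import SpectraMatrix  # local import to avoid a cycle

    ssc = np.asarray(ssc, dtype=float)
    ph = np.asarray(ph, dtype=float)
    if ssc.shape != ph.shape or ssc.ndim != 1:
        raise ParameterError("ssc and ph must be 1-D vectors of equal length")
    n = ssc.size
    rng = np.random.default_rng(config.seed)
    clean = config.baseline[None, :] * 10.0 ** (-_absorbance(ssc, ph, config))
    slope = rng.uniform(*config.scatter_slope_range, size=n)
    offset = rng.uniform(*config.scatter_offset_range, size=n)
    observed = offset[:, None] + slope[:, None] * clean
    if config.noise_sd > 0:
        observed = observed + rng.normal(0.0, config.noise_sd, size=observed.shape)
    ids = [f"sample_{i:04d}" for i in range(n)]
    matrix = SpectraMatrix(values=observed, wavelengths=config.wavelengths.copy(), sample_ids=ids)
    truth = GroundTruth(ssc=ssc.copy(), ph=ph.copy(), slope=slope, offset=offset, clean_spectra=clean)
    return matrix, truth


def generate_scene_cube(spectra, layout_rows: int = 3, layout_cols: int = 5,
                        disk_radius: int = 10, background_level: float = 0.05,
                        seed: int = 0, cell_size: int | None = None):
    """Paint spectra as non-overlapping disks on a uniform dark background.

    Emulates fruit evenly placed on the imaging platform (3 rows x 5
    columns by default).  Each disk carries its sample's spectrum at every
    pixel; returns ``(ReflectanceCube, masks)`` with the pixel-true boolean
    masks in row-major order.  ``seed`` jitters disk centres slightly
    within their cells without ever allowing overlap.  ``cell_size``
    overrides the per-fruit cell edge; a cell too small for the disk
    raises :class:`GeometryError`.
    """
    from .cube_io import ReflectanceCube

    n = spectra.values.shape[0]
    if layout_rows * layout_cols < n:
        raise ParameterError("layout too small for the number of spectra")
    if disk_radius < 1:
        raise ParameterError("disk_radius must be >= 1")
    if cell_size is None:
        gap = max(4, disk_radius // 2)
        cell = 2 * disk_radius + 2 * gap
    else:
        cell = int(cell_size)
        gap = (cell - 2 * disk_radius) // 2
        if gap < 1:
            raise GeometryError("disks would overlap: cell_size too small for disk_radius")
    height = layout_rows * cell
    width = layout_cols * cell
    n_bands = spectra.values.shape[1]
    rng = np.random.default_rng(seed)
    data = np.full((height, width, n_bands), float(background_level))
    yy, xx = np.mgrid[0:height, 0:width]
    masks = []
    jitter_max = gap // 2
    for k in range(n):
        r, c = divmod(k, layout_cols)
        cy = r * cell + cell // 2 + int(rng.integers(-jitter_max, jitter_max + 1))
        cx = c * cell + cell // 2 + int(rng.integers(-jitter_max, jitter_max + 1))
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= disk_radius ** 2
        data[mask] = spectra.values[k]
        masks.append(mask)
    cube = ReflectanceCube(data=data, wavelengths=spectra.wavelengths.copy())
    return cube, masks


def generate_dataset(config: SyntheticConfig | None = None):
    """Convenience wrapper: targets + spectra in one call.

    Target vectors are drawn from the default truncated normals with
    seeds derived from ``config.seed``; returns
    ``(SpectraMatrix, TargetTable, GroundTruth)``.
    """
    from .pipeline import TargetTable

    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    ssc = generate_targets(config.n_samples, SSC_MEAN, SSC_SD, SSC_LO, SSC_HI, rng)
    ph = generate_targets(config.n_samples, PH_MEAN, PH_SD, PH_LO, PH_HI, rng)
    matrix, truth = generate_spectra(ssc, ph, config)
    targets = TargetTable(ssc=ssc, ph=ph, sample_ids=list(matrix.sample_ids))
    return matrix, targets, truth
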