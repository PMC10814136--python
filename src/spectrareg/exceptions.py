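"""Exception hierarchy shared across the package."""


class SpectraRegError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SpectraRegError, ValueError):
    """Invalid argument value or inconsistent argument combination."""


class FormatError(SpectraRegError, ValueError):
    """Malformed on-disk data (e.g. an ENVI header/binary mismatch)."""


class GeometryError(SpectraRegError, ValueError):
    """Impossible scene geometry (e.g. overlapping sample disks)."""


class DegenerateSampleError(SpectraRegError, ValueError):
    """A per-sample fit collapsed (e.g. near-zero MSC slope)."""

    def __init__(self, sample_ids, message=None):
        self.sample_ids = list(sample_ids)
        super().__init__(message or f"degenerate samples: {self.sample_ids}")


class DivergedTrainingError(SpectraRegError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch, message=None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")


class UnsupportedModelError(SpectraRegError, TypeError):
    """Operation not defined for this model family (e.g. Grad-CAM without a conv front-end)."""
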