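"""Exception hierarchy shared across the pipeline."""


class DigiwellError(Exception):
    """Base class for all package-specific errors."""


class DomainError(DigiwellError, ValueError):
    """An argument is outside its physically meaningful domain."""


class CapacityError(DomainError):
    """The well grid is too small to hold the requested number of wells."""


class DegenerateGeometryError(DomainError):
    """Corner points are collinear/duplicated; no projective map exists."""


class OutOfFrameError(DigiwellError):
    """Mapped wells (or their apertures) fall outside the image bounds."""

    def __init__(self, well_indices, message=None):
        self.well_indices = list(well_indices)
        super().__init__(
            message
            or f"{len(self.well_indices)} well(s) fall outside the image frame "
            f"(first few: {self.well_indices[:5]})"
        )


class EmptyApertureError(DigiwellError):
    """A well aperture contains zero pixel centers."""


class FormatError(DigiwellError):
    """An input file does not match the expected on-disk format."""


class SampleSizeError(DomainError):
    """Too few observations to fit the intensity mixture."""


class DegenerateDataError(DomainError):
    """All intensity values identical; mixture fit undefined."""


class SaturationError(DomainError):
    """All wells positive: the Poisson occupancy estimate is undefined."""


class SchemaError(DigiwellError):
    """Tabular input is missing required columns or channels mismatch."""


class UndefinedMetricError(DigiwellError):
    """A metric (sensitivity, specificity, AUC...) is undefined for the input."""


class UndefinedCurveError(DigiwellError):
    """No positive detections anywhere: standard-curve fit undefined."""
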