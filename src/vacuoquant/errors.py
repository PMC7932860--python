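"""Exception hierarchy for the vacuolization-quantification pipeline."""


class VacuoquantError(Exception):
    """Base class for all package errors."""


class ParameterError(VacuoquantError, ValueError):
    """An argument or configuration value violates its contract."""


class ShapeError(VacuoquantError, ValueError):
    """Two arrays that must share spatial dimensions do not."""


class EmptyMaskError(VacuoquantError, ValueError):
    """Both masks empty where the dice coefficient is undefined (0/0)."""


class DataError(VacuoquantError, ValueError):
    """A dataset is missing required fields (masks, labels, classes)."""


class SegmentationFailureError(VacuoquantError, RuntimeError):
    """The predicted cytoplasm mask is empty; the cell cannot be classified."""


class QuantificationFailureError(VacuoquantError, RuntimeError):
    """Every cell of a smear was excluded; no percentage can be reported."""


class DegenerateDataError(VacuoquantError, ValueError):
    """Input data carry no usable variation for the requested statistic."""


class ModelError(VacuoquantError, RuntimeError):
    """A model bundle is untrained or incompatible with the input."""


class ManifestError(VacuoquantError, ValueError):
    """A manifest file is malformed or references missing images."""
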