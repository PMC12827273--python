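"""Exception hierarchy shared across petcog modules."""


class PetcogError(Exception):
    """Base class for all petcog errors."""


class ConfigurationError(PetcogError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DomainError(PetcogError, ValueError):
    """An argument outside its mathematical domain (non-positive dose, k <= 0, ...)."""


class AlignmentError(PetcogError, ValueError):
    """Volume and atlas shapes do not match."""


class EmptyRegionError(PetcogError, KeyError):
    """A requested atlas label has no voxels."""

    def __init__(self, label):
        self.label = label
        super().__init__(f"atlas label {label} has no voxels")


class SampleSizeError(PetcogError, ValueError):
    """Too few observations for the requested computation."""


class RankDeficiencyError(PetcogError, ValueError):
    """A design or correlation submatrix is singular / collinear."""


class OrientationConflictError(PetcogError, ValueError):
    """Background-knowledge tiers contradict a data-driven edge orientation."""


class ModelStateError(PetcogError, RuntimeError):
    """Model used before fitting, or with inputs it was not fitted for."""


class DivergenceError(PetcogError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch, message=None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class UndefinedMetricError(PetcogError, ValueError):
    """A metric is undefined for the given inputs (e.g. R^2 with constant targets).

    Carries the metrics that *are* defined in ``partial_metrics``.
    """

    def __init__(self, message, partial_metrics=None):
        self.partial_metrics = partial_metrics
        super().__init__(message)
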