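"""Exception hierarchy for olftes.

Every documented failure mode raises a distinct subclass so callers can
discriminate programmatically; all inherit from :class:`OlftesError`.
"""


class OlftesError(Exception):
    """Base class for all olftes errors."""


class InvalidGeometryError(OlftesError, ValueError):
    """Geometric preconditions violated (e.g. non-decreasing sphere radii)."""


class InvalidParameterError(OlftesError, ValueError):
    """A scalar parameter is outside its admissible range."""


class ResolutionError(OlftesError, ValueError):
    """Voxel spacing too coarse to realize a requested structure."""


class UnknownTissueError(OlftesError, KeyError):
    """A tissue label has no conductivity-table entry."""


class EmptyRoiError(OlftesError, ValueError):
    """An operation requires a non-empty region of interest."""


class UnknownLandmarkError(OlftesError, KeyError):
    """Landmark name not in the fiducial set or supported 10-10 labels."""


class UnknownMontageError(OlftesError, KeyError):
    """Montage id outside the six standard definitions."""


class GeometryConflictError(OlftesError, ValueError):
    """Stamped electrode footprints overlap."""


class PlacementError(OlftesError, ValueError):
    """Electrode anchor could not be resolved onto the phantom surface."""


class FloatingDomainError(OlftesError, ValueError):
    """A source-carrying conductive component has no path to ground."""


class SingularSystemError(OlftesError, ValueError):
    """No ground face: the Neumann problem is singular."""


class ConvergenceError(OlftesError, RuntimeError):
    """Iterative solver failed to reach tolerance.

    Carries the residual history in ``residuals``.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals if residuals is not None else []


class StateError(OlftesError, RuntimeError):
    """Operation requires a solved field that is not available."""


class OutOfDomainError(OlftesError, ValueError):
    """A sample point lies outside the solved conductive domain."""


class DegeneratePathError(OlftesError, ValueError):
    """Axon control points do not define a path of positive length."""


class InsufficientSamplesError(OlftesError, ValueError):
    """Too few samples for a second-difference operator."""


class NormalizationError(OlftesError, ValueError):
    """Cannot normalize an all-zero profile set."""


class SingularityError(OlftesError, ValueError):
    """Evaluation point coincides with a point-source singularity."""


class ConfigurationError(OlftesError, ValueError):
    """Mismatched or invalid run configuration."""


class PipelineError(OlftesError, RuntimeError):
    """A pipeline stage failed; message names the stage and montage."""
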