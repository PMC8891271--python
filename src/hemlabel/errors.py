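"""Exception hierarchy for the label-transfer pipeline.

All pipeline-specific failures derive from :class:`HemlabelError` so callers
can catch one base class; each subclass also derives from the closest builtin
(``ValueError``, ``OSError``) so generic handling keeps working.
"""


class HemlabelError(Exception):
    """Base class for all pipeline errors."""


class ImageReadError(HemlabelError, OSError):
    """A slide or mask file could not be read."""


class LevelError(HemlabelError, ValueError):
    """Requested pyramid level does not exist in the image file."""


class CoordinateError(HemlabelError, ValueError):
    """A tile or mask coordinate lies outside the image."""


class DegenerateInputError(HemlabelError, ValueError):
    """Input carries no usable signal (e.g. constant image or histogram)."""


class InsufficientTissueError(HemlabelError, ValueError):
    """Too few tissue pixels for a stain or mask estimate."""


class RankError(HemlabelError, ValueError):
    """A stain matrix is singular / rank deficient."""


class RegistrationError(HemlabelError, RuntimeError):
    """The registration optimizer diverged or produced a non-finite metric."""


class TransformError(HemlabelError, ValueError):
    """A transform cannot be applied (e.g. non-invertible affine)."""


class TrainingError(HemlabelError, ValueError):
    """The classifier cannot be trained on the given manifest."""


class MissingArtifactError(HemlabelError, FileNotFoundError):
    """A pipeline stage input produced by an earlier stage is missing."""
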