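"""Exception hierarchy for the mrsidh pipeline.

Every error raised on a user-facing path derives from :class:`MrsidhError`
so callers (CLI, batch drivers) can distinguish pipeline failures from bugs.
"""


class MrsidhError(Exception):
    """Base class for all mrsidh pipeline errors."""


class InvalidParameterError(MrsidhError, ValueError):
    """A configuration or function argument violates its contract."""


class SpectrumFormatError(MrsidhError, ValueError):
    """A spectrum text file does not match the expected format."""


class FeatureMatrixError(MrsidhError, ValueError):
    """A feature matrix file or object violates its invariants."""


class AlignmentError(MrsidhError, RuntimeError):
    """Chemical-shift referencing failed (e.g. featureless search window)."""


class ClassBalanceError(MrsidhError, ValueError):
    """Too few samples of one class for the requested operation."""


class DegenerateDataError(MrsidhError, ValueError):
    """Training data admit no meaningful classifier (e.g. identical rows)."""


class ConfigMismatchError(MrsidhError, ValueError):
    """Artifacts produced under different configurations were mixed."""
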