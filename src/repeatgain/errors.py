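"""Exception hierarchy for the repeatgain package.

Errors are split by the pipeline stage that raises them so callers (and the
CLI) can map failures to actionable messages.
"""


class RepeatGainError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RepeatGainError):
    """A required column is missing or a file does not parse."""


class EmptyInputError(RepeatGainError):
    """An input table or trace contains no usable rows."""


class DuplicateKeyError(RepeatGainError):
    """A key expected to be unique (e.g. sample_id) occurs more than once."""


class ValidationError(RepeatGainError):
    """Metadata violates an invariant (e.g. baseline at nonzero timepoint)."""


class CalibrationError(RepeatGainError):
    """Too few or degenerate standards for a per-run size calibration."""


class RunMismatchError(RepeatGainError):
    """A calibration model was applied to a trace from a different run."""


class EmptyTraceError(RepeatGainError):
    """A trace has no peak with positive height."""


class DegenerateWeightError(RepeatGainError):
    """All peak heights are zero, so a weighted mean is undefined."""


class PairingError(RepeatGainError):
    """A lineage lacks the baseline sample needed for repeat-gain metrics."""


class DegenerateDesignError(RepeatGainError):
    """All timepoints sit at week 0, so no through-origin slope exists."""


class NormalizationError(RepeatGainError):
    """A clone lacks vehicle replicates (or their mean is zero)."""


class SampleSizeError(RepeatGainError):
    """A statistical contrast was requested with fewer than two values."""


class ScaleError(RepeatGainError):
    """Ratio-scale statistics requested on non-positive values."""


class DegenerateOutcomeError(RepeatGainError):
    """The top two editing outcomes carry zero read mass."""


class CoordinateError(RepeatGainError):
    """A junction or variant coordinate falls outside its sequence."""


class ConfigError(RepeatGainError):
    """A simulation or run configuration is invalid."""


class RenderError(RepeatGainError):
    """Rendering produced no visible signal (e.g. bias zeroed all heights)."""
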