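"""Exception hierarchy for the breathval pipeline.

All pipeline errors derive from :class:`BreathvalError` so callers can catch
one base class; the leaves distinguish malformed inputs from statistically
degenerate ones (single-class labels, zero variance) and from contract
violations (unnormalized tables, mutated frozen models).
"""


class BreathvalError(Exception):
    """Base class for all breathval errors."""


class FormatError(BreathvalError):
    """A delimited input file does not have the expected columns/layout."""


class ValidationError(BreathvalError):
    """A value violates a domain invariant (negative intensity, bad config)."""


class MissingInternalStandardError(BreathvalError):
    """No internal-standard (m/z 95) record found in the configured window."""


class StateError(BreathvalError):
    """An operation was applied to an object in the wrong state
    (e.g. binning an unnormalized ion table)."""


class DegenerateInputError(BreathvalError):
    """A statistic is undefined on the input (single-class labels,
    empty group)."""


class ConsistencyError(BreathvalError):
    """Two objects that must refer to the same features/samples do not."""


class InsufficientDataError(BreathvalError):
    """Too few observations for the requested statistic."""


class UndefinedCorrelationError(BreathvalError):
    """Correlation requested on a zero-variance vector."""


class BlindingViolationError(BreathvalError):
    """A frozen model was mutated between fitting and blinded reporting."""
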