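"""Exception hierarchy for force-curve analysis failures.

All rbcmech errors derive from :class:`RbcMechError` so callers can catch the
package's failures without masking programming errors.
"""


class RbcMechError(Exception):
    """Base class for all rbcmech errors."""


class FormatError(RbcMechError):
    """A curve or table file does not conform to the declared dialect."""


class ValidationError(RbcMechError, ValueError):
    """An in-memory object violates a structural invariant."""


class ParameterError(RbcMechError, ValueError):
    """A configuration value is outside its admissible range."""


class SegmentationError(RbcMechError):
    """The acquisition protocol could not be recovered from the piezo trace."""


class ContactDetectionError(RbcMechError):
    """No contact signature could be located on an approach segment."""


class FitError(RbcMechError):
    """A least-squares fit failed to converge or lacked usable data."""


class ProtocolError(RbcMechError):
    """A relaxation protocol is inconsistent (missing segments, unreachable force)."""


class InvalidGeometryError(RbcMechError):
    """SLS inversion denominator J + dc - db is non-positive (no equilibrium spring)."""


class InvalidAmplitudeError(RbcMechError):
    """SLS inversion denominator kc*db - k2*A is non-positive (no Maxwell spring)."""


class AggregationError(RbcMechError):
    """No valid per-curve results remain to aggregate."""


class SpecError(RbcMechError, ValueError):
    """A simulation specification is internally inconsistent."""


class DegenerateDataError(RbcMechError):
    """A statistical routine received data with no usable variation."""
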