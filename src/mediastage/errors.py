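"""Exception hierarchy."""


class MediastageError(Exception):
    """Base class for all package errors."""


class DiagramError(MediastageError):
    """An influence diagram violates a structural invariant."""


class CapacityError(MediastageError):
    """An operation would materialize a table larger than the configured bound."""


class ElicitationError(MediastageError):
    """Invalid inputs to a second-order distribution recipe."""


class FitError(ElicitationError):
    """A distribution fit did not converge within its search bracket."""


class InconsistentEvidenceError(MediastageError):
    """Evidence with probability zero under the imposed policies."""
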