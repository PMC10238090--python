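"""Exception hierarchy shared across the package."""


class XenovocalError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(XenovocalError, ValueError):
    """An input violates a documented precondition."""


class UnknownProfileError(XenovocalError, KeyError):
    """Requested species preset does not exist; message lists valid names."""


class MissingChannelError(XenovocalError, KeyError):
    """A required channel role is absent from the recording."""


class InsufficientEventsError(XenovocalError):
    """Too few events (clicks/CAPs/pulses) for the requested computation."""


class FitFailureError(XenovocalError):
    """Nonlinear fit failed to converge from every start.

    The ``partial`` attribute carries the best partial result, if any.
    """

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


class PairingError(XenovocalError):
    """Paired pre/post inputs do not match in length/order."""


class ResolutionMismatchError(XenovocalError):
    """Spectra with different segment lengths cannot be averaged."""


class FormatError(XenovocalError):
    """On-disk container is malformed or inconsistent with its sidecar."""


class DegenerateFitWarning(UserWarning):
    """A fitted model collapsed to a degenerate configuration."""
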