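"""Exception hierarchy shared across the toolkit."""


class RTDKitError(Exception):
    """Base class for all toolkit errors."""


class InvalidInputError(RTDKitError, ValueError):
    """A supplied value or data set violates an operation's preconditions."""


class ContractError(RTDKitError, ValueError):
    """Two objects that must agree (grids, lengths, normalization) do not."""


class RangeError(RTDKitError, ValueError):
    """A requested quantity falls outside the representable/studied range."""


class DependencyError(RTDKitError, RuntimeError):
    """An upstream result required by a sequential step is missing."""


class FitFailureError(RTDKitError, RuntimeError):
    """The optimizer failed to converge after all multi-starts."""


class DegeneracyError(RTDKitError, ValueError):
    """A regression design matrix is rank deficient."""
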