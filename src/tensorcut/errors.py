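"""Exception hierarchy shared across the package."""


class TensorcutError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(TensorcutError, ValueError):
    """A value violates an operation's input contract (non-finite, non-SPD, shape mismatch)."""


class ConfigurationError(TensorcutError, ValueError):
    """A run is ill-posed: empty seed set, bad parameter range, unresolvable option."""


class FormatError(TensorcutError, ValueError):
    """A file does not match the documented on-disk convention."""


class ContractViolationError(TensorcutError, ValueError):
    """An operation was called outside its stated preconditions (e.g. non-neighbor pair)."""


class SpecificationError(TensorcutError, ValueError):
    """A phantom specification is geometrically or physically inconsistent."""
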