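"""Exception hierarchy shared across the package."""


class ChronometError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChronometError):
    """A file does not conform to the expected tabular layout."""


class DuplicateKeyError(ChronometError):
    """The same (subject, time point, metabolite) key occurs more than once."""


class LookupFailure(ChronometError, KeyError):
    """A requested subject, time point or metabolite does not exist."""

    def __str__(self) -> str:  # KeyError quotes its repr; keep the message readable
        return Exception.__str__(self)


class DomainError(ChronometError):
    """Input values violate a mathematical precondition."""


class ConfigError(ChronometError):
    """A configuration object or file is invalid."""


class InsufficientOverlapError(ChronometError):
    """Two trajectories share too few observed time points to be compared."""


class ValidationError(ChronometError):
    """Network-validation input is unusable (e.g. no mappable nodes)."""


class NumericError(ChronometError):
    """A numerical routine failed to converge or hit a singular matrix."""
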