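"""Exception hierarchy.

Exit-code mapping for the CLI: InputError -> 2, SizeCapError -> 3.
"""


class AceForestError(Exception):
    """Base class for all package errors."""


class InputError(AceForestError):
    """Malformed or inconsistent input data (files, profiles, names)."""


class ContractError(AceForestError):
    """A caller violated an operation's precondition."""


class ConsistencyError(ContractError):
    """A labeling contradicts an observed leaf value."""


class SizeCapError(AceForestError):
    """Instance exceeds a solver's configured size cap."""


class ReductionDomainError(AceForestError):
    """Instance outside the domain of a graph reduction (e.g. non-green table)."""


class ClassificationError(AceForestError):
    """Weight table cannot be classified as green or red."""


class DegenerateTableError(AceForestError):
    """Weight table has no usable probability mass even after smoothing."""
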