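"""Exception hierarchy shared across the package."""


class ToxsetsError(Exception):
    """Base class for all errors raised by toxsets."""


class FormatError(ToxsetsError):
    """A text input (GMT or expression table) violates its format contract."""


class InputError(ToxsetsError):
    """Structurally valid input that cannot be used (empty table, unknown set)."""


class DomainError(ToxsetsError):
    """A value is outside its mathematical domain (empty score list, bad p)."""


class DegenerateNullError(DomainError):
    """A null distribution cannot be sampled (sample size >= background size)."""


class CombinatorialLimitError(DomainError):
    """Exhaustive enumeration was refused because C(N, n) exceeds the bound."""
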