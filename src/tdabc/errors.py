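"""Exception hierarchy for pathway, costing and sensitivity errors."""


class TdabcError(Exception):
    """Base class for all package errors."""


class ValidationError(TdabcError, ValueError):
    """An input violates a structural invariant (duplicate id, negative
    duration, non-positive capacity, infeasible truncation bounds, ...)."""


class CrossReferenceError(TdabcError, KeyError):
    """A record refers to an entity that does not exist in the registry
    (unknown resource in a staffing map, orphan patient id, missing rate)."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class DomainError(TdabcError, ValueError):
    """An operation was invoked outside its mathematical domain (CCR of a
    consumable, shares of a zero total, degenerate frontier, ...)."""
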