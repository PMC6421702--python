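"""Exception hierarchy shared across the package."""


class TriageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TriageError):
    """A profile, design or template is internally inconsistent."""


class InputError(TriageError):
    """User-supplied data is outside the documented domain."""


class TemplateError(TriageError):
    """A dialogue template cannot be rendered (unresolved placeholder, bad branch)."""


class DesignError(TriageError):
    """A trial design is infeasible (e.g. more scenarios than crossing cells)."""


class RankDeficiencyError(TriageError):
    """A model design matrix is singular; carries the name of the aliased term."""

    def __init__(self, term: str):
        self.term = term
        super().__init__(f"design matrix is rank deficient: term {term!r} is aliased")


class ReliabilityUndefinedError(InputError):
    """Cronbach's alpha is undefined (zero total-score variance)."""


class UsageError(TriageError):
    """An operation was called with incompatible objects (e.g. non-nested fits)."""
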