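"""Exception hierarchy shared across the package."""


class MonoddeError(Exception):
    """Base class for all package errors."""


class ValidationError(MonoddeError, ValueError):
    """A domain object violates its invariants.

    ``problems`` lists every violation found, not just the first.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class DomainError(MonoddeError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class UnattainableRateError(MonoddeError, ValueError):
    """A requested rate exceeds (or equals) the supremum of mu(s)."""


class UsageError(MonoddeError, ValueError):
    """An operation was called in a way that makes no sense for its inputs."""
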