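"""Exception types shared across the pipeline stages."""


class FireHIAError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FireHIAError, ValueError):
    """A scalar parameter violates its domain (e.g. negative rate, RR <= 0)."""


class MissingDataError(FireHIAError, KeyError):
    """A district lacks a population or rate entry and no fill policy applies."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class CRSError(FireHIAError, ValueError):
    """Coordinate reference systems disagree or a transform is unknown."""


class ValidationError(FireHIAError, ValueError):
    """An input file violates its schema; carries the list of violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))
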