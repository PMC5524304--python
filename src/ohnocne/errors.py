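"""Exception hierarchy shared across the package."""


class OhnocneError(Exception):
    """Base class for all package errors."""


class ParseError(OhnocneError):
    """A file did not conform to its declared format."""


class IntegrityError(OhnocneError):
    """Parsed data violated a structural invariant (e.g. ragged alignment rows)."""


class ValidationError(OhnocneError):
    """User-supplied values or parameters are out of range or inconsistent."""


class InsufficientDataError(OhnocneError):
    """Too few observations to run the requested statistic."""


class FitError(OhnocneError):
    """Maximum-likelihood optimisation failed; carries the best attempt if any."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit
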