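"""Exception hierarchy shared across the package."""


class MrpipeError(Exception):
    """Base class for all package errors."""


class ConfigError(MrpipeError, ValueError):
    """A configuration problem: missing mapped column, bad threshold, bad YAML."""


class InputError(MrpipeError, ValueError):
    """Malformed or unusable input data (zero valid rows, r2 out of range, ...)."""


class DomainError(MrpipeError, ValueError):
    """Arguments outside an operation's mathematical domain (n <= 2, k too small, ...)."""


class DegenerateDesignError(DomainError):
    """A regression design without leverage (all exposure effects identical)."""


class NoInstrumentsError(MrpipeError):
    """No valid instruments survived selection/harmonization for a trait pair.

    Pipelines catch this and mark the trait ``not_evaluable`` rather than aborting.
    """
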