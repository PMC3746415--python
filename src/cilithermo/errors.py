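"""Exception types shared across the pipeline."""


class CilithermoError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(CilithermoError):
    """A cell or cohort specification violates its invariants."""


class InsufficientDataError(CilithermoError):
    """An operation received fewer observations than it requires."""


class StratumInfeasibleError(CilithermoError):
    """Rejection sampling could not place a cell in its responsiveness stratum."""


class IntegrityError(CilithermoError):
    """An input table violates structural integrity (duplicates, gaps, bad values)."""


class DesignError(CilithermoError):
    """A factorial design is deficient (empty cell, incomplete within-factor)."""
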