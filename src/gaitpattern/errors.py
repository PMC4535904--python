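"""Exception hierarchy for the gaitpattern pipeline."""


class GaitPatternError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GaitPatternError, ValueError):
    """A configuration object violates its invariants."""


class ParameterError(GaitPatternError, ValueError):
    """An operation received an out-of-range or inconsistent argument."""


class SchemaError(GaitPatternError, ValueError):
    """An input table is missing required columns or has malformed rows."""


class DuplicateTrialError(GaitPatternError, ValueError):
    """Two trials share the same (subject, condition, side, trial) key."""


class ConsistencyError(GaitPatternError, ValueError):
    """Trials disagree on waveform length or angle layout."""


class DegenerateDataError(GaitPatternError, ValueError):
    """Data has no variance where a scale estimate is required."""


class InsufficientDataError(GaitPatternError, ValueError):
    """Too few trials to compute the requested quantity."""


class InfeasibleDropError(GaitPatternError, ValueError):
    """Requested trial removal would empty a subject/condition/side cell."""
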