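"""Exception types shared across the package."""


class FaersPvError(Exception):
    """Base class for all package errors."""


class SchemaError(FaersPvError):
    """A required column is missing from an input table."""


class ContractViolationError(FaersPvError):
    """An operation was called on data violating its precondition
    (e.g. Haldane-correcting an already corrected table, or running an
    exact test on non-integer counts)."""


class ConfigError(FaersPvError):
    """Invalid synthetic-data or pipeline configuration."""


class DegenerateDataError(FaersPvError):
    """The data admit no answer: empty lnROR matrix, constant PCA column,
    zero marginal in an association table, too few observations."""
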