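"""Exception hierarchy shared across the pipeline."""


class AreadepError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AreadepError, ValueError):
    """Invalid configuration: bad bounds, unknown names, mismatched recipes."""


class ValidationError(AreadepError, ValueError):
    """Invalid data passed to a computation (negative counts, missing values...)."""


class SchemaError(AreadepError, ValueError):
    """One or more input-table schema violations, aggregated.

    ``problems`` holds every violation found, not just the first.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("schema validation failed:\n" + "\n".join(f"  - {p}" for p in self.problems))


class UnmappedUnitError(AreadepError, KeyError):
    """Legacy geography units missing from the crosswalk."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"legacy units missing from crosswalk: {self.missing}")


class EstimationError(AreadepError, RuntimeError):
    """A statistical fit failed to converge."""


class CalibrationError(AreadepError, ValueError):
    """The exponential-transform constant has no admissible solution."""


class UndefinedRatioError(AreadepError, ZeroDivisionError):
    """Observed events with zero expected events: the ratio is undefined."""


class DegenerateScaleError(AreadepError, ValueError):
    """Min-max normalization of a constant column: every area is tied."""


class UndefinedCorrelationError(AreadepError, ValueError):
    """Correlation of a constant input is undefined."""
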