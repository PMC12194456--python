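"""Exception hierarchy for the dkabase pipeline.

Each family maps to a distinct CLI exit code (see :mod:`dkabase.cli`).
"""


class DkabaseError(Exception):
    """Base class for all package errors."""


class DomainError(DkabaseError):
    """An input violates a mathematical or physiological precondition."""


class MissingDataError(DkabaseError):
    """A required field or panel is absent; the message names it."""

    def __init__(self, field: str, context: str = ""):
        self.field = field
        msg = f"missing required field: {field}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class RegistryError(DkabaseError):
    """A fluid name cannot be resolved in the composition registry."""


class SchemaError(DkabaseError):
    """A CSV file violates its declared schema (message carries row/column)."""


class DegenerateDataError(DkabaseError):
    """A statistical routine received data it cannot test (constant column,
    single group, too few observations)."""


class CollinearityError(DegenerateDataError):
    """Regression design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "rank-deficient design matrix; linearly dependent columns: "
            + ", ".join(self.columns)
        )


class ConfigError(DkabaseError):
    """A configuration file or object is invalid (unknown key, bad value)."""


class SimulationError(DkabaseError):
    """The synthetic-cohort generator produced or detected a non-physical
    state; the message names the offending parameter."""
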