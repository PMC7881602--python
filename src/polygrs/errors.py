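"""Exception hierarchy. CLI exit codes: config 2, data 3, degeneracy 4."""


class PolygrsError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(PolygrsError):
    """Invalid configuration or parameters."""

    exit_code = 2


class SchemaError(PolygrsError):
    """Malformed or inconsistent input data."""

    exit_code = 3


class InvalidParameterError(ConfigError):
    """Numeric parameter outside its domain (e.g. OR <= 0, f outside (0,1))."""


class InvalidDosageError(SchemaError):
    """Dosage outside {0, 1, 2, missing}."""


class FlaggedSubjectError(SchemaError):
    """Subject cannot be scored (e.g. every panel dosage missing)."""


class DegenerateStatisticError(PolygrsError):
    """A statistic is undefined on the given data (zero margin, one group...)."""

    exit_code = 4
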