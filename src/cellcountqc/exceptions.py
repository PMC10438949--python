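"""Exception hierarchy for cellcountqc."""


class CellCountQCError(Exception):
    """Base class for all package errors."""


class SchemaError(CellCountQCError):
    """Input table does not match the documented schema."""


class DesignError(CellCountQCError):
    """Study design is invalid or inconsistent between datasets."""


class FitError(CellCountQCError):
    """A model fit cannot be computed from the data provided."""


class ConfigError(CellCountQCError):
    """An analysis or simulation configuration value is invalid."""
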