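"""Exception hierarchy for pdstart."""


class PdstartError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PdstartError):
    """A required column is missing or the column mapping is invalid."""


class PanelDataError(PdstartError):
    """The panel violates a data invariant (grid, baseline row, duplicates, monotonicity)."""


class EstimationError(PdstartError):
    """An estimator cannot produce an identified estimate on the given data."""


class InferenceError(PdstartError):
    """Bootstrap inference is unreliable (too many failed replicates)."""


class ConfigError(PdstartError):
    """A run configuration is invalid."""
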