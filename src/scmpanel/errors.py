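"""Exception hierarchy for panel validation and pipeline configuration."""


class ScmPanelError(Exception):
    """Base class for all package errors."""


class SchemaError(ScmPanelError):
    """Input table is missing required columns or has unusable dtypes."""


class IntegrityError(ScmPanelError):
    """Input data violates structural constraints (duplicates, negatives...)."""


class ConfigurationError(ScmPanelError):
    """Study configuration is inconsistent (windows, mappings, treated id)."""


class ScaleError(ScmPanelError):
    """A brand has a degenerate (zero) pre-period scale under the chosen method."""


class SolverError(ScmPanelError):
    """The weight optimizer failed to produce a feasible solution."""
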