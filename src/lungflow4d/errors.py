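"""Exception types shared across the pipeline."""


class LungflowError(Exception):
    """Base class for pipeline errors."""


class DegenerateTreeError(LungflowError):
    """Airway tree has no endpoints (a segment needs a parent to count)."""


class SeedError(LungflowError):
    """Flood-fill seed lies outside the requested intensity window."""


class ConfigurationError(LungflowError):
    """Inconsistent geometry or parameters (e.g. overlapping compartments)."""


class ParameterError(LungflowError):
    """Non-physical model parameter (e.g. R <= 0 or C <= 0)."""


class StructuralError(LungflowError):
    """Graph structure violates tree requirements (e.g. a cycle)."""
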