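"""Error hierarchy shared across the package.

Solver infeasibility is *data* (a trajectory that ends early), never an
exception; only setup, format and contract violations raise.
"""


class AdfbaError(Exception):
    """Base class for all package errors."""


class FormatError(AdfbaError):
    """A file could not be parsed as the expected format."""


class ModelValidationError(AdfbaError):
    """A metabolic model violates a structural invariant."""


class ReactionLookupError(AdfbaError):
    """A reaction id was requested but is absent from the model."""


class ConfigurationError(AdfbaError):
    """Invalid simulation or analysis configuration."""


class ScheduleError(AdfbaError):
    """A bounds/concentration schedule is malformed or incomplete."""


class ContractError(AdfbaError):
    """A user callback or analysis input violated its contract."""


class IntegrationError(AdfbaError):
    """State update drove a tracked concentration meaningfully negative."""
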