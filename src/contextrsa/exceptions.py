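"""Exception hierarchy for contextrsa."""


class ContextRSAError(Exception):
    """Base class for all contextrsa errors."""


class FormatError(ContextRSAError, ValueError):
    """A file does not conform to the expected container/table layout."""


class ValidationError(ContextRSAError, ValueError):
    """A domain object violates one of its invariants."""


class ZeroVarianceError(ContextRSAError, ValueError):
    """A pattern or dissimilarity vector is constant, so a correlation is undefined."""


class DesignError(ContextRSAError, ValueError):
    """An experimental-design parameter is infeasible (e.g. odd scene count)."""


class ConfigurationError(ContextRSAError, ValueError):
    """User configuration is inconsistent (e.g. alias targets a missing concept)."""


class PipelineStageError(ContextRSAError, RuntimeError):
    """A pipeline stage failed; the message names the subject and stage."""
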