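"""Exception hierarchy shared by all panlineage modules."""


class PanlineageError(Exception):
    """Base class for all errors raised by panlineage."""


class FormatError(PanlineageError):
    """A file could not be parsed (malformed header, wrong dialect, ...)."""


class ValidationError(PanlineageError, ValueError):
    """Inputs are parseable but violate an invariant (non-binary cell,
    duplicate identifier, conflicting lineage assignment, ...)."""


class ConfigurationError(PanlineageError, ValueError):
    """A parameter combination leaves nothing to analyse (e.g. every
    lineage dropped by the size filter)."""
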