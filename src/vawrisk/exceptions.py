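"""Exception hierarchy for vawrisk."""


class VawriskError(Exception):
    """Base class for all vawrisk errors."""


class FormatError(VawriskError):
    """Input table does not match the expected column layout."""


class ParseError(VawriskError):
    """A cell could not be parsed; message carries row and column."""


class ConfigError(VawriskError):
    """Model configuration violates an invariant (weights, thresholds, lambda)."""


class EmptyTableError(VawriskError):
    """No classifiable records remain after exclusions."""


class JoinError(VawriskError):
    """Identifiers could not be matched between two inputs."""
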