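"""Exception hierarchy shared across the pipeline stages."""


class CladecallError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CladecallError, ValueError):
    """Invalid user-supplied configuration (counts, class names, lengths...)."""


class MissingDataError(CladecallError, ValueError):
    """Required measurements are absent; the message names clone and gene."""


class DegenerateDataError(CladecallError, ValueError):
    """Input is structurally valid but too degenerate for the operation
    (e.g. fewer than three points for an ellipse, singular covariance)."""
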