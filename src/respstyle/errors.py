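"""Exception taxonomy.

Every error raised by this package falls into one of four classes so that
pipeline stages can classify failures (config | data | numeric | model/IO)
in logs and reports.
"""


class RespstyleError(Exception):
    """Base class for all package errors."""

    category = "generic"


class ConfigError(RespstyleError):
    """Invalid configuration: bad labels, malformed constraint vectors, ..."""

    category = "config"


class DataError(RespstyleError):
    """Invalid input data or contract violation at a call boundary."""

    category = "data"


class NumericError(RespstyleError):
    """Numerical-domain failure: non-finite logits, singular Hessians, ..."""

    category = "numeric"


class ModelError(RespstyleError):
    """Model-level inconsistency, e.g. a non-PSD latent correlation matrix."""

    category = "model"
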