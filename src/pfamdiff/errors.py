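"""Exception types raised across the package."""


class PfamDiffError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PfamDiffError, ValueError):
    """An input table violates a structural invariant (duplicate ids,
    negative counts, dangling gene references, malformed categories)."""


class EstimationError(PfamDiffError, ValueError):
    """A statistical quantity cannot be estimated from the data given
    (e.g. no Pfam expressed in every community, too few usable Pfams)."""


class ConfigError(PfamDiffError, ValueError):
    """A synthetic-data configuration is internally inconsistent."""
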