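"""Exception types shared across the pipeline stages."""


class QuasipopError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(QuasipopError, ValueError):
    """A spec/config object violates its invariants."""


class CapacityError(ConfigurationError):
    """A request exceeds what the genome can accommodate (e.g. too many SNP loci)."""


class DegenerateInputError(QuasipopError, ValueError):
    """Input is structurally valid but statistically degenerate for the operation."""


class MalformedInputError(QuasipopError, ValueError):
    """An input record is inconsistent with the declared reference or pairing."""
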