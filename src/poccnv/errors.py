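"""Exception types shared across the package."""


class PoccnvError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PoccnvError, ValueError):
    """A genome/simulation/run configuration value is unusable."""


class InvalidSpecError(PoccnvError, ValueError):
    """A karyotype specification is internally inconsistent or out of bounds."""


class SchemaError(PoccnvError, ValueError):
    """An input file does not match its documented schema."""


class BoundsError(PoccnvError, ValueError):
    """A genomic coordinate falls outside the genome model."""
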