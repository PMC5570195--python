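"""Exception hierarchy shared across the package."""


class MotifcoreError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MotifcoreError):
    """A text input could not be parsed (wrong column count, bad number, ...)."""


class ValidationError(MotifcoreError):
    """Parsed input violates a domain constraint (bad symbol, length mismatch, ...)."""


class ConfigError(MotifcoreError):
    """An option combination or configuration value is inconsistent."""


class EmptyCandidateError(MotifcoreError):
    """A ligand admits no core placement under the current motif length and indel policy."""


class DegenerateDataError(MotifcoreError):
    """The data make an operation ill-defined (e.g. min == max in a rescaling)."""


class TrainingError(MotifcoreError):
    """Numerical failure during network training (non-finite gradients, empty fold, ...)."""


class ModelFormatError(MotifcoreError):
    """A model file has an incompatible format version."""


class IntegrityError(MotifcoreError):
    """A model file is truncated or its checksum does not match its payload."""
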