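"""Exception hierarchy for the pipeline.

Errors are split by origin: bad arguments (ParameterError), bad or
inconsistent data (DataError), impossible configuration
(ConfigurationError), file-format problems (FormatError), and calling
preprocessing stages out of order (StateError).
"""


class NirsConnError(Exception):
    """Base class for all package errors."""


class ParameterError(NirsConnError, ValueError):
    """An argument is outside its admissible range."""


class DataError(NirsConnError, ValueError):
    """Input data violate an invariant (negative intensity, NaN, ...)."""


class ConfigurationError(NirsConnError, ValueError):
    """Configuration is internally inconsistent or unusable."""


class FormatError(NirsConnError, ValueError):
    """A file does not conform to the expected on-disk structure."""


class StateError(NirsConnError, RuntimeError):
    """A preprocessing stage was invoked out of chain order."""
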