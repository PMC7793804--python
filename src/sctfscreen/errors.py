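"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and its
subclass FormatError) -> 3, NoTFContrastError -> 4.
"""


class SctfError(Exception):
    """Base class for all package errors."""


class ConfigError(SctfError):
    """Invalid parameter or configuration value."""


class DataError(SctfError):
    """Input data violates a contract (duplicates, empty result, bad values)."""


class FormatError(DataError):
    """A file does not conform to its declared format."""


class NoTFContrastError(SctfError):
    """The TF shows no expression contrast across clusters.

    Raised when the transcription factor's cluster-mean profile is constant,
    i.e. the transfection-induced dose heterogeneity the screen relies on is
    absent from the data.
    """
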