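"""Exception hierarchy shared across the package."""


class FlipsiteError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(FlipsiteError):
    """A structure file record could not be parsed (message names the line)."""


class RTFParseError(FlipsiteError):
    """A CHARMM-RTF-dialect record could not be parsed."""


class SchemaError(FlipsiteError):
    """A tabular input is missing required columns or has bad values."""


class StructureError(FlipsiteError):
    """Molecular data are internally inconsistent (counts, bonds, residues)."""


class ConfigurationError(FlipsiteError):
    """Required annotations or options are missing for the requested analysis."""


class UnsupportedFormatError(FlipsiteError):
    """The input uses a format or feature outside the supported subset."""
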