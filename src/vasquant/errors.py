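"""Exception hierarchy shared across the pipeline."""


class VasquantError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VasquantError):
    """A parameter or config key is missing, unknown, or out of range."""


class FormatError(VasquantError):
    """An input file has an unsupported layout or bit depth."""


class DegenerateInputError(VasquantError):
    """The input is valid but the requested quantity is undefined on it
    (e.g. Otsu threshold of a constant image, coverage of an empty vessel
    mask)."""
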