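"""Exception hierarchy for the solvent toolbox."""


class SussolError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SussolError):
    """A column or property name does not match the declared schema."""


class ParseError(SussolError):
    """A CSV cell could not be parsed; the message names row and column."""


class MissingDataError(SussolError):
    """An operation hit a MISSING value it cannot handle."""


class DegenerateDataError(SussolError):
    """The data is too incomplete or too small for the requested operation."""
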