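"""Exception hierarchy shared across the package."""


class DrugNetError(Exception):
    """Base class for all drugnet errors."""


class ParseError(DrugNetError, ValueError):
    """A malformed line in an input table; the message names the line number."""


class ParameterError(DrugNetError, ValueError):
    """A parameter outside its documented domain."""


class UnknownEntityError(DrugNetError, KeyError):
    """A node, drug or disease identifier that the network/catalogs do not contain."""
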