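"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ``InputError`` -> 2,
``DegenerateDataError`` -> 3, anything else -> 1.
"""


class NetvulnError(Exception):
    """Base class for all package errors."""


class InputError(NetvulnError):
    """Malformed input file, invalid parameter, or violated precondition."""


class FormatError(InputError):
    """A file does not conform to the expected on-disk format."""


class ParameterError(InputError):
    """A numeric or structural parameter is out of its allowed range."""


class DegenerateDataError(NetvulnError):
    """Input is syntactically valid but statistically unusable
    (e.g. all features zero-variance, regular degree distribution)."""
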