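"""Exception hierarchy for user-facing errors.

``InputError`` covers problems with the user's data (missing files,
inconsistent tables, unknown identifiers); ``FormatError`` covers files
that cannot be parsed as the declared format. The CLI maps both to exit
code 1; anything else is an internal error (exit 2).
"""


class CTAError(Exception):
    """Base class for all errors raised by this package."""


class InputError(CTAError):
    """The input data are inconsistent or reference unknown entities."""


class FormatError(InputError):
    """A file does not conform to its declared format."""
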