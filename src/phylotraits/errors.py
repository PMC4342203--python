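"""Exception hierarchy.

Validation errors signal bad user input (CLI exit code 2); anything else
propagates as an internal error (exit code 1).
"""


class PhylotraitsError(Exception):
    """Base class for all package errors."""


class ValidationError(PhylotraitsError):
    """Input violates a documented precondition."""


class FormatError(PhylotraitsError):
    """A file could not be parsed in the declared format."""
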