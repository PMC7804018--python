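"""Exception hierarchy shared across the package."""


class HrpfError(Exception):
    """Base class for all package errors."""


class FormatError(HrpfError):
    """A structure or table file violates the expected format."""


class ValidationError(HrpfError):
    """Input values violate a documented precondition."""
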