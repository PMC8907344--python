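"""Exception hierarchy shared across the package."""


class AcetylomeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(AcetylomeError):
    """A file or table does not conform to the documented schema."""


class ValidationError(AcetylomeError):
    """An argument or configuration violates a documented invariant."""
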