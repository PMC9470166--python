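"""Exception hierarchy shared across the package."""


class SipstructError(Exception):
    """Base class for all package errors."""


class ValidationError(SipstructError, ValueError):
    """An input violated a documented invariant (exit code 2 at the CLI)."""


class ParseError(SipstructError, ValueError):
    """A file could not be parsed; message names the offending line/field."""


class DegenerateFitError(SipstructError, ValueError):
    """A model fit was requested on data that cannot identify its parameters."""
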