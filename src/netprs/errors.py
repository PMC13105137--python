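"""Exception types shared across the package."""


class NetPRSError(Exception):
    """Base class for all package errors."""


class FormatError(NetPRSError):
    """A summary-statistics file violates the expected tabular format."""


class HarmonizationError(NetPRSError):
    """Allele harmonization against the reference panel failed."""


class SolverError(NetPRSError):
    """The coordinate-descent solver produced a non-finite update."""
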