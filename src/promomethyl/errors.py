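"""Exception types raised across the package."""


class PromomethylError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PromomethylError, ValueError):
    """Invalid parameter, specification or table content."""


class ParseError(PromomethylError, ValueError):
    """Malformed input file; message carries file context (line number etc.)."""


class QCUnavailableError(PromomethylError):
    """A QC metric was requested but its inputs are absent.

    Raised instead of silently returning zero so that a missing
    non-CpG tally is never mistaken for perfect bisulfite conversion.
    """
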