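"""Exception hierarchy.

``DataError`` covers violated invariants of in-memory objects (negative
counts, unmatched samples, zero calibration counts); ``FormatError`` covers
malformed files.  The CLI maps both to exit status 1; argument misuse exits 2.
"""


class SCMLError(Exception):
    """Base class for all package errors."""


class FormatError(SCMLError):
    """A file could not be parsed; the message names the offending cell."""


class DataError(SCMLError):
    """An invariant of the data model is violated."""
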