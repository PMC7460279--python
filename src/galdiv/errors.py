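"""Exception hierarchy.

``GaldivError`` marks user-facing errors (bad input files, unknown ids,
invalid thresholds); anything else escaping the API is an internal bug.
"""


class GaldivError(Exception):
    """Base class for user-facing errors."""


class ParseError(GaldivError):
    """Malformed input file; message names the file and offending line."""


class QCError(GaldivError):
    """Quality-control produced an unusable dataset (e.g. empty after QC)."""
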