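"""Package-wide exception types.

``ValidationError`` marks bad inputs or configuration (CLI exit code 2),
``DegenerateSignalError`` marks recordings that cannot be processed at all,
e.g. a constant pupil trace with zero velocity variance (CLI exit code 3).
"""


class ValidationError(ValueError):
    """Invalid input data, file format, or configuration."""


class DegenerateSignalError(RuntimeError):
    """Signal too degenerate to analyze (e.g. zero velocity variance)."""
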