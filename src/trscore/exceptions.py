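"""Exception hierarchy for trscore.

All input problems raise :class:`FormatError` (structurally unreadable) or
:class:`ValidationError` (readable but violates an invariant); numerical
failures in model fitting raise :class:`SeparationError` or
:class:`ConvergenceError`.
"""


class TrscoreError(Exception):
    """Base class for all trscore errors."""


class FormatError(TrscoreError):
    """A file or table does not have the expected structure."""


class ValidationError(TrscoreError):
    """A table is structurally fine but violates a domain invariant."""


class SeparationError(TrscoreError):
    """Perfect or quasi-perfect separation in a logistic fit."""


class ConvergenceError(TrscoreError):
    """IRLS failed to converge within the iteration budget."""
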