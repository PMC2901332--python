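"""Exception hierarchy.

User-facing errors (bad configuration, out-of-range queries) derive from
:class:`DialsimUserError`; failures of the numerics (non-finite derivatives,
failed step-halving checks) derive from :class:`NumericalError`.  The CLI maps
these onto exit codes 1 and 2 respectively.
"""


class DialsimError(Exception):
    """Base class for all package errors."""


class DialsimUserError(DialsimError, ValueError):
    """Invalid input, configuration or query (CLI exit code 1)."""


class RangeError(DialsimUserError):
    """Query outside the tabulated/valid range; no extrapolation is done."""


class NumericalError(DialsimError, ArithmeticError):
    """Numerical failure: non-finite state or unmet accuracy contract (exit 2)."""


class AccuracyError(NumericalError):
    """Step-halving convergence check failed; advise a smaller time step."""
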