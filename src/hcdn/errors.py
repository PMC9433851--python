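"""Exception hierarchy.

Validation problems (bad shapes, missing columns, inconsistent inputs) and
numerical problems (singular covariances, non-converged samplers) are kept
distinct so callers — including the CLI — can map them to different exit
codes.
"""


class HcdnError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(HcdnError, ValueError):
    """Inputs violate a documented precondition."""


class NumericalError(HcdnError, ArithmeticError):
    """A computation failed for numerical reasons (singularity, divergence)."""
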