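"""Exception hierarchy for condkin.

All condkin errors derive from :class:`CondkinError` so callers can catch
library failures without masking programming errors.
"""


class CondkinError(Exception):
    """Base class for all condkin errors."""


class SpecValidationError(CondkinError, ValueError):
    """A domain object violated one of its invariants.

    The message names the offending field.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DegenerateSystemError(CondkinError, ValueError):
    """The two phases have equal composition (phi_I == phi_II).

    A two-compartment description is meaningless here; use the homogeneous
    reference path (``simulate_homogeneous``) instead.
    """


class SolverFailureError(CondkinError, RuntimeError):
    """The stiff integrator failed or produced an unacceptable state.

    Carries the time at which the failure was detected (``t_fail``) when
    known.  Tighter tolerances or nondimensionalised rates usually help.
    """

    def __init__(self, message: str, t_fail: float | None = None):
        self.t_fail = t_fail
        if t_fail is not None:
            message = f"{message} (at t={t_fail:.6g})"
        super().__init__(message)


class NotConvergedError(CondkinError, RuntimeError):
    """A trajectory did not reach its plateau; asymptotic values undefined.

    Raised instead of silently returning transient values.
    """


class NoCharacteristicScaleError(CondkinError, ValueError):
    """All nucleation rate constants are zero; no aggregation time scale."""


class IncompleteRowError(CondkinError, ValueError):
    """A literature-system row is missing its reaction orders."""
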