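"""Exception hierarchy for comfba."""


class ComfbaError(Exception):
    """Base class for all comfba errors."""


class ModelFormatError(ComfbaError):
    """A model file could not be parsed; names the offending element."""


class ModelError(ComfbaError):
    """A parsed model violates a structural invariant (e.g. no biomass reaction)."""


class ConfigurationError(ComfbaError):
    """A community/run configuration references unknown ids or invalid values."""


class UnboundedError(ComfbaError):
    """An optimization problem is unbounded.

    ``ray_member`` names a reaction that can carry unbounded flux when one
    could be identified.
    """

    def __init__(self, message: str, ray_member: str | None = None):
        super().__init__(message)
        self.ray_member = ray_member


class InfeasibleError(ComfbaError):
    """A problem that must be feasible (e.g. FVA base solve) is not."""

    def __init__(self, message: str, violated: list[str] | None = None):
        super().__init__(message)
        #: best-effort list of constraint labels implicated in the infeasibility
        self.violated = violated or []


class BigMError(ComfbaError):
    """A big-M certificate kept failing after the allowed doublings."""


class ConvergenceError(ComfbaError):
    """The spatial branch-and-bound did not close the gap within its node budget."""
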