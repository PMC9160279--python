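"""Exception hierarchy shared across the package."""


class BiogaskitError(Exception):
    """Base class for all package-specific errors."""


class FeedstockValidationError(BiogaskitError, ValueError):
    """A characterization table is malformed or violates an invariant."""


class ClosureError(FeedstockValidationError):
    """Element or component percentages do not close to ~100%."""


class InfeasibleFeedstockError(BiogaskitError, ValueError):
    """Elemental composition too oxidized/reduced for the stoichiometric model."""


class UnitError(BiogaskitError, ValueError):
    """Unknown or inconsistent physical units."""


class FitError(BiogaskitError, RuntimeError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_params: dict | None = None):
        super().__init__(message)
        self.last_params = last_params or {}


class StageError(BiogaskitError, RuntimeError):
    """Pipeline stage failure, tagged with the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
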