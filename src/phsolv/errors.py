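"""Exception hierarchy for phsolv."""


class PhsolvError(Exception):
    """Base class for all phsolv errors."""


class InputError(PhsolvError, ValueError):
    """Invalid user-supplied input (negative totals, bad shapes, ...)."""


class SolverError(PhsolvError, RuntimeError):
    """Equilibrium solver failed to converge.

    Carries a ``diagnostics`` dict with the last residuals and iteration
    counts so failures can be triaged without re-running.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PhaseSelectionError(PhsolvError, RuntimeError):
    """Solid-phase selection oscillated or exceeded its iteration cap."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history or []


class CalibrationError(PhsolvError, ValueError):
    """Electrode map has no root in the search bracket."""


class DomainError(PhsolvError, ValueError):
    """Request outside the mathematical domain (no coexistence point, ...)."""


class UnderdeterminedError(PhsolvError, ValueError):
    """Fewer weighted observations than free constants."""


class RefineError(PhsolvError, RuntimeError):
    """Nonlinear refinement failed; carries the optimizer trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class DegenerateFitError(PhsolvError, ValueError):
    """Segmented fit collapsed to (near-)parallel lines."""


class FormatError(PhsolvError, ValueError):
    """Malformed delimited-text input."""


class FormulaParseError(PhsolvError, ValueError):
    """Chemical formula could not be parsed."""


class ResultsIOError(PhsolvError, IOError):
    """Result object cannot be written (empty object, unwritable path)."""
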