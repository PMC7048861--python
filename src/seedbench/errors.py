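"""Exception types shared across the package."""


class SeedbenchError(Exception):
    """Base class for all package errors."""


class ParameterError(SeedbenchError, ValueError):
    """Invalid generation or simulation parameter."""


class CategoryError(SeedbenchError, ValueError):
    """Unknown or structurally impossible network category."""


class CalibrationError(SeedbenchError, RuntimeError):
    """Clustering target outside the achievable bracket of the generator."""

    def __init__(self, target: float, bracket: tuple[float, float]):
        self.target = target
        self.bracket = bracket
        super().__init__(
            f"clustering target {target:.3f} outside achievable bracket "
            f"[{bracket[0]:.3f}, {bracket[1]:.3f}]"
        )


class StrategyError(SeedbenchError, ValueError):
    """Unknown strategy name or invalid seeding request."""


class UnreachedError(SeedbenchError, RuntimeError):
    """A spreading run hit max_steps before infecting the whole component."""
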