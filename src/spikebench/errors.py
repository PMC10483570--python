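"""Exception types shared across the package."""


class SpikebenchError(Exception):
    """Base class for package errors."""


class NumericalOverflowError(SpikebenchError, ValueError):
    """A step kernel received or produced a non-finite membrane potential."""


class SimulationDivergence(SpikebenchError, RuntimeError):
    """A time-stepped run went non-finite; carries the offending step index."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"state became non-finite at step {step}")


class ConfigError(SpikebenchError, ValueError):
    """Malformed or incomplete run/regime configuration."""
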