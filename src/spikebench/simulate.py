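"""Time-stepped simulation: stimulus protocols, trace recording and the
per-sample constant-current drive used by the classification benchmark.

Simulation is fixed-step forward Euler throughout (no event-driven spike
timing).  A trace run records the membrane potential after every update
together with the spike steps; the benchmark drive runs a model from its
initial state under a constant current and counts spikes, re-initializing the
state for every sample so no history leaks between samples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, NumericalOverflowError, SimulationDivergence
from .models import Model, NeuronState, SimulationGrid

__all__ = ["StimulusProtocol", "SpikeRecord", "run_trace",
           "simulate_sample", "simulate_batch"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Input-current protocol on a simulation grid.

    ``kind="constant"`` applies ``amplitude`` at every step; ``kind="pulse"``
    applies it on steps ``onset_step <= i < offset_step`` and zero outside.
    """

    kind: str
    amplitude: float
    grid: SimulationGrid
    onset_step: int = 0
    offset_step: int | None = None

    def __post_init__(self):
        if self.kind not in ("constant", "pulse"):
            raise ConfigError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "pulse":
            off = self.offset_step if self.offset_step is not None else self.grid.n_steps
            if not 0 <= self.onset_step <= off <= self.grid.n_steps:
                raise ConfigError(
                    "pulse window must satisfy 0 <= onset <= offset <= n_steps")

    def current_at(self, step: int) -> float:
        if self.kind == "constant":
            return self.amplitude
        off = self.offset_step if self.offset_step is not None else self.grid.n_steps
        return self.amplitude if self.onset_step <= step < off else 0.0

    @classmethod
    def pulse_fractions(cls, amplitude: float, grid: SimulationGrid,
                        onset_frac: float = 0.1, offset_frac: float = 0.6
                        ) -> "StimulusProtocol":
        """Pulse spanning a fraction of the run (defaults: 10% to 60%)."""
        return cls(kind="pulse", amplitude=amplitude, grid=grid,
                   onset_step=int(onset_frac * grid.n_steps),
                   offset_step=int(offset_frac * grid.n_steps))


@dataclass
class SpikeRecord:
    """Per-step membrane trace, spike steps and reproduction metadata."""

    trace: np.ndarray
    spike_steps: np.ndarray
    dt: float
    amplitude: float
    params_snapshot: dict
    seed: int | None = None

    @property
    def spike_times(self) -> np.ndarray:
        return (self.spike_steps + 1) * self.dt

    def to_frame(self) -> pd.DataFrame:
        steps = np.arange(len(self.trace))
        spiked = np.zeros(len(self.trace), dtype=bool)
        spiked[self.spike_steps] = True
        return pd.DataFrame({
            "step": steps,
            "time": (steps + 1) * self.dt,
            "V": self.trace,
            "spiked": spiked.astype(int),
            "amplitude": np.where(spiked, self.amplitude, 0.0),
        })

    def write_csv(self, csv_path: str | Path) -> None:
        """CSV of the trace plus a JSON sidecar with parameters and seed."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = {"params": self.params_snapshot, "seed": self.seed,
                   "dt": self.dt, "spike_amplitude": self.amplitude}
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def _params_snapshot(model: Model) -> dict:
    snap = {k: v for k, v in dataclasses.asdict(model.params).items()
            if v is not None}
    snap.update(model=model.name, variant=model.variant, dt=model.dt)
    return snap


def run_trace(model: Model, protocol: StimulusProtocol,
              seed: int | None = None) -> SpikeRecord:
    """Run a model over a stimulus protocol and record the membrane trace.

    Aborts with :class:`SimulationDivergence` (carrying the step index) if the
    state goes non-finite mid-run.
    """
    grid = protocol.grid
    if abs(grid.dt - model.dt) > 1e-12:
        raise ConfigError(
            f"protocol dt {grid.dt} does not match model dt {model.dt}")
    rng = np.random.default_rng(seed) if seed is not None else None
    state = model.init_state()
    trace = np.empty(grid.n_steps)
    spike_steps = []
    for i in range(grid.n_steps):
        I = protocol.current_at(i)
        try:
            state, spiked = model.step(state, I, grid, rng=rng)
        except NumericalOverflowError as exc:
            raise SimulationDivergence(i) from exc
        trace[i] = state.V
        if spiked:
            spike_steps.append(i)
    return SpikeRecord(trace=trace, spike_steps=np.asarray(spike_steps, dtype=int),
                       dt=grid.dt, amplitude=model.amplitude,
                       params_snapshot=_params_snapshot(model), seed=seed)


def simulate_batch(model: Model, currents: np.ndarray, window_steps: int,
                   seed: int | None = None) -> np.ndarray:
    """Spike counts for a batch of independent neurons under constant drive.

    Every element of ``currents`` drives its own neuron, initialized fresh
    from the model's initial state, for ``window_steps`` Euler steps at the
    model's regime time step.  Returns the per-neuron spike count.
    """
    if window_steps < 1:
        raise ConfigError(f"window_steps must be >= 1, got {window_steps}")
    currents = np.asarray(currents, dtype=float)
    grid = SimulationGrid(dt=model.dt, n_steps=window_steps)
    rng = np.random.default_rng(seed) if seed is not None else None
    state = model.init_state(batch=currents.size)
    counts = np.zeros(currents.size, dtype=np.int64)
    flat = currents.ravel()
    for _ in range(window_steps):
        state, spiked = model.step(state, flat, grid, rng=rng)
        counts += spiked
    return counts.reshape(currents.shape)


def simulate_sample(model: Model, current: float, window_steps: int,
                    seed: int | None = None) -> int:
    """Spike count of one fresh neuron under a constant current."""
    return int(simulate_batch(model, np.asarray([current]), window_steps,
                              seed=seed)[0])
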