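"""Arithmetic-operation accounting for each model's state update.

Each model's per-step cost is tabulated once, from the itemized operation
descriptions of the source analysis (e.g. the LIF update costs one
multiplication, one subtraction and one comparison; the Hodgkin-Huxley update
costs 18 additions, 15 multiplications and 3 divisions).  The counters are
bookkeeping attached to the ordinary step: `counted_step` advances the model
and returns the per-step cost, and `count_run` accumulates it over a run --
linear in the number of steps, since every tabulated cost is
state-independent.  Spike-reset branch costs are not itemized in the source
and are not counted.  Wall-clock or memory profiling is out of scope: these
tallies are a hardware-independent proxy for relative update cost only.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import ConfigError
from .models import Model, NeuronState, SimulationGrid
from .simulate import StimulusProtocol

__all__ = ["OperationCount", "PER_STEP_COSTS", "counted_step", "count_run"]


@dataclass(frozen=True)
class OperationCount:
    """Itemized arithmetic-operation tally; ``total`` is the component sum."""

    additions: int = 0
    subtractions: int = 0
    multiplications: int = 0
    divisions: int = 0
    exponential_evaluations: int = 0
    comparisons: int = 0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{f.name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return (self.additions + self.subtractions + self.multiplications
                + self.divisions + self.exponential_evaluations + self.comparisons)

    def __add__(self, other: "OperationCount") -> "OperationCount":
        return OperationCount(*(getattr(self, f.name) + getattr(other, f.name)
                                for f in fields(self)))

    def __mul__(self, k: int) -> "OperationCount":
        return OperationCount(*(getattr(self, f.name) * k for f in fields(self)))

    __rmul__ = __mul__


#: Documented per-step cost of each model's update.
PER_STEP_COSTS: dict[str, OperationCount] = {
    "LIF": OperationCount(multiplications=1, subtractions=1, comparisons=1),
    "NLIF": OperationCount(multiplications=3, subtractions=1, comparisons=1,
                           additions=2),
    "AdEx": OperationCount(multiplications=1, additions=4),
    "HH": OperationCount(additions=18, multiplications=15, divisions=3),
    "IFSFA": OperationCount(multiplications=2, additions=2, subtractions=1,
                            comparisons=1),
    "QIF": OperationCount(multiplications=1, additions=1, comparisons=1),
    "ThetaNeuron": OperationCount(multiplications=2, additions=2),
    "Izhikevich": OperationCount(multiplications=2, additions=2, subtractions=2),
    "SRM": OperationCount(additions=3, divisions=2),
}


def counted_step(model: Model, state: NeuronState, I, grid: SimulationGrid | None = None,
                 rng: np.random.Generator | None = None):
    """Ordinary model step plus its per-step operation cost."""
    if model.name not in PER_STEP_COSTS:
        raise ConfigError(f"no per-step cost registered for model {model.name!r}")
    new_state, spiked = model.step(state, I, grid, rng=rng)
    return new_state, spiked, PER_STEP_COSTS[model.name]


def count_run(model: Model, n_steps: int,
              protocol: StimulusProtocol | None = None,
              rng: np.random.Generator | None = None) -> OperationCount:
    """Accumulated operation count over an ``n_steps`` run.

    The model is actually stepped (under the protocol's current, or zero
    input when none is given) so that a run that would diverge raises, but
    the tally itself is the documented per-step cost times the steps taken.
    """
    if n_steps < 0:
        raise ConfigError(f"n_steps must be >= 0, got {n_steps}")
    grid = SimulationGrid(dt=model.dt, n_steps=n_steps)
    state = model.init_state()
    total = OperationCount()
    for i in range(n_steps):
        I = protocol.current_at(i) if protocol is not None else 0.0
        state, _, delta = counted_step(model, state, I, grid, rng=rng)
        total = total + delta
    return total
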