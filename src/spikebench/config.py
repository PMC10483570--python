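"""Parameter-regime loading and run configuration.

Two regimes ship with the package as YAML documents whose keys mirror the
source parameter tables row-for-row (``regimes/table2.yaml`` -- the trace
regime; ``regimes/table3.yaml`` -- the benchmark regime).  "X" cells of the
tables are simply absent keys.  This module translates the human-readable row
labels into the parameter fields of each model family and fills the few
values a regime leaves open (documented inline).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Any

import yaml

from .errors import ConfigError
from .models import MODEL_NAMES, canonical_name

REGIMES = ("table2", "table3")

_TIME_STEP = "Time step"
_POPULATION = "No. of neurons"

# row label -> parameter field, per model, for the benchmark regime
_BENCH_MAP: dict[str, dict[str, str | None]] = {
    "LIF": {"Tau": "tau", "Reset potential": "V_reset",
            "Threshold value": "V_th", "Initial potential": "V_init"},
    "NLIF": {"Tau": "tau", "Reset potential": "V_reset",
             "Threshold value": "V_th", "Initial potential": "V_init",
             "Alpha": "alpha", "Beta": "beta"},
    "AdEx": {"Tau": "tau_m", "Reset potential": "V_reset",
             "Initial potential": "V_init", "Rheobase potential": "V_rheo",
             "Threshold potential": "V_spike", "Slope factor": "Delta_T"},
    "HH": {"Tau": None,  # printed for HH but not part of its equations
           "Reset potential": "V_reset", "Initial potential": "V_init",
           "Activation variable for potassium": "n0",
           "Activation variable for sodium": "m0",
           "Inactivation variable for sodium": "h0",
           "Maximum conductances gNa": "g_Na",
           "Maximum conductances gK": "g_K",
           "Maximum conductances gL": "g_L",
           "Sodium rev. pot.": "E_Na", "Potassium rev. pot.": "E_K",
           "Leak conductance rev. pot.": "E_L"},
    "IFSFA": {"Tau": "tau_m", "Reset potential": "V_rest",
              "Threshold value": "V_th", "Initial potential": "V_init",
              "Slope factor": "Delta_T",
              "Adaptation time constant": "tau_w",
              "Adaptation conductance": "A", "Adaptation control": "b"},
    "QIF": {"Tau": "tau", "Reset potential": "V_reset",
            "Threshold value": "V_th", "Initial potential": "V_init",
            "Beta": "beta"},
    "ThetaNeuron": {"Tau": "tau_m", "Reset potential": "V_reset",
                    "Threshold value": "V_th", "Initial potential": "V_init"},
    "SRM": {"Tau": "tau_s", "Reset potential": "V_reset",
            "Threshold value": "V_th", "Initial potential": "V_init",
            "Synaptic time constants": "tau_r"},
    "Izhikevich": {"Threshold value": "V_peak", "Initial potential": "V_init",
                   "Recovery variable": "U_init", "Time scale RV": "a",
                   "Sensitivity RV": "b", "After-spike reset MP": "c",
                   "After-spike reset RV": "d"},
}

# row label -> parameter field, per model, for the trace regime
_TRACE_MAP: dict[str, dict[str, str | None]] = {
    "LIF": {"Time constant": "tau", "Membrane resistance": "R_m",
            "Threshold value": "V_th", "Reset membrane potential": "V_reset",
            "Initial potential": "V_init", "Leak conductance": "g_leak"},
    "NLIF": {"Time constant": "tau", "Membrane resistance": "R_m",
             "Threshold value": "V_th", "Reset membrane potential": "V_reset",
             "Initial potential": "V_init", "Leak conductance": "g_leak"},
    "AdEx": {"Time constant": "tau_m", "Membrane resistance": "R_m",
             "Threshold value": "V_th", "Reset membrane potential": "V_reset",
             "Initial potential": "V_init", "Leak conductance": "g_leak",
             "Adaptation time constant": "tau_w",
             "Adaptation conductance": "a", "Adaptation increment": "b"},
    "HH": {"Threshold value": "V_detect",
           "Reset membrane potential": "V_reset",
           "Initial potential": "V_init", "Leak conductance": "g_L",
           "Membrane capacitance": "C_m", "Sodium conductance": "g_Na",
           "Potassium conductance": "g_K", "Sodium reversal": "E_Na",
           "Potassium reversal": "E_K", "Leak reversal": "E_L"},
    "Izhikevich": {"Time constant": "tau", "Membrane resistance": "R_m",
                   "Threshold value": "V_peak",
                   # the explicit after-spike reset row supersedes the generic
                   # reset row for this model
                   "Reset membrane potential": None,
                   "Initial potential": "V_init",
                   "Refractory period": "refractory",
                   "Recovery variable": "a", "Sensitivity (RV/MP)": "b",
                   "After-spike reset": "c", "After-spike reset (RV/AV)": "d"},
    "SRM": {"Time constant": "tau",
            "Membrane resistance": None,  # printed; unused by the trace equations
            "Threshold value": "V_th", "Reset membrane potential": "V_reset",
            "Initial potential": "V_init", "Refractory period": "tau_ref",
            "Leak conductance": "g_L", "Membrane capacitance": "C_m",
            "Input conductance": "g", "Synaptic time constant": "tau_s",
            "Synaptic reversal potential": "E_s", "Synaptic weight": "A"},
    "IFSFA": {"Membrane resistance": "R_m", "Threshold value": "V_peak",
              "Reset membrane potential": "V_r",
              "Initial potential": "V_init",
              "Adaptation time constant": "tau_w",
              "Adaptation conductance": "a",
              "Adaptation increment": "b",
              "Membrane capacitance": "C_m", "Sensitivity (RV/MP)": "K",
              "After-spike reset": "c", "After-spike reset (RV/AV)": "d"},
    "QIF": {"Threshold value": "V_th", "Reset membrane potential": "V_reset",
            "Initial potential": "V_init", "Refractory period": "tau_ref",
            "Membrane capacitance": "C_m"},
    "ThetaNeuron": {"Time constant": "tau", "Threshold value": "theta",
                    "Reset membrane potential": "V_r",
                    "Initial potential": "V_init",
                    "Input conductance": "g"},
}

_MAPS = {"table2": _TRACE_MAP, "table3": _BENCH_MAP}


def _load_regime(regime: str) -> dict[str, dict[str, Any]]:
    if regime not in REGIMES:
        raise ConfigError(f"unknown regime {regime!r}; known: {REGIMES}")
    text = resources.files("spikebench.regimes").joinpath(f"{regime}.yaml").read_text()
    return yaml.safe_load(text)


def regime_variant(name: str, regime: str) -> str:
    """Formulation variant a regime's parameter column describes."""
    name = canonical_name(name)
    if regime == "table2":
        return "B"
    if name == "QIF":
        # the benchmark column (tau, beta) parameterizes the quadratic form
        return "C"
    if name == "HH":
        return "B"  # single HH formulation
    return "A"


def regime_params(name: str, regime: str) -> tuple[dict[str, Any], float]:
    """Translate a regime column into model parameter fields.

    Returns ``(field_values, dt)``.  Raises ConfigError for models missing
    from the regime or for rows that have no meaning for the model.
    """
    name = canonical_name(name)
    table = _load_regime(regime)
    if name not in table:
        raise ConfigError(f"regime {regime!r} has no column for model {name}")
    rows = dict(table[name])
    dt = float(rows.pop(_TIME_STEP, 0.1))
    rows.pop(_POPULATION, None)
    label_map = _MAPS[regime][name]
    values: dict[str, Any] = {}
    for label, value in rows.items():
        if label not in label_map:
            raise ConfigError(f"row {label!r} is not applicable to {name} in {regime}")
        fld = label_map[label]
        if fld is not None:
            values[fld] = float(value)
    # regime-level gaps the tables leave open
    if name == "HH" and regime == "table3":
        # the benchmark column prints no spike-detection threshold; reuse the
        # source's only printed HH threshold (-66 mV, trace regime), which
        # sits below the -65 mV reset/initial value and makes the benchmark
        # HH a degenerate always-firing unit -- consistent with its printed
        # chance-level benchmark accuracy
        values.setdefault("V_detect", -66.0)
    if name == "Izhikevich" and regime == "table2":
        # no initial recovery value printed; start u at its nullcline b*V_init
        values.setdefault("U_init", values["b"] * values["V_init"])
    return values, dt


def regime_population(name: str, regime: str) -> int:
    """Population size stated by the regime (used by the random-weight
    population mapping); defaults to 1000."""
    table = _load_regime(regime)
    name = canonical_name(name)
    return int(table.get(name, {}).get(_POPULATION, 1000))


@dataclass
class RunConfig:
    """A reproducible run description: regime, models, dataset and seeds."""

    regime: str = "table3"
    models: tuple[str, ...] = MODEL_NAMES
    n_per_class: int = 1000
    mapping: str = "unit"
    window_steps: int = 100
    seeds: tuple[int, ...] = tuple(range(10))
    out_dir: str = "results"
    verbosity: int = 1

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ConfigError(f"unknown regime {self.regime!r}")
        if not self.seeds:
            raise ConfigError("seeds must be nonempty")
        self.models = tuple(canonical_name(m) for m in self.models)
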