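"""Step-update kernels for nine single-neuron spiking models.

Every model advances its state by one explicit forward-Euler step and reports
whether a spike was emitted.  Two formulation variants are carried side by
side, because the source experiments use two distinct parameter regimes:

* variant ``"A"`` -- the dimensionless *benchmark* formulation (thresholds
  near 1), used by the two-class classification benchmark;
* variant ``"B"`` -- the *trace* formulation (time in ms, potentials in mV),
  used for the pulse-response membrane-trace experiment.

The quadratic integrate-and-fire model has a third variant ``"C"``, the
genuinely quadratic update ``dV/dt = (-V + beta*V^2 + I)/tau``; the benchmark
regime parameterizes that form.

All kernels are written elementwise so that the state fields may be either
Python floats (single neuron) or equal-shaped numpy arrays (a batch of
independent neurons stepped in lockstep).  Kernels are pure: they return a new
:class:`NeuronState` and never mutate their input.

Spike convention: a membrane potential exactly at threshold spikes (``>=``
comparison), uniformly across models.  During a refractory period the
potential is held at the reset value and no spike can be emitted; refractory
durations are stored as integer step counts ``round(tau_ref / dt)`` and
decremented before the update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Any, Callable, Mapping, Union

import numpy as np

from .errors import ConfigError, NumericalOverflowError

Array = Union[float, np.ndarray]

__all__ = [
    "SimulationGrid",
    "NeuronState",
    "LIFParams",
    "NLIFParams",
    "AdExParams",
    "IFSFAParams",
    "ThetaParams",
    "HHParams",
    "QIFParams",
    "IzhParams",
    "SRMParams",
    "Model",
    "MODEL_NAMES",
    "SPIKE_AMPLITUDES",
    "make_model",
    "lif_step",
    "nlif_step",
    "adex_step",
    "ifsfa_step",
    "theta_step",
    "hh_step",
    "qif_step",
    "izh_step",
    "srm_step",
]


# ---------------------------------------------------------------------------
# grid and state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform time grid: step duration ``dt`` and a non-negative step count."""

    dt: float
    n_steps: int = 0

    def __post_init__(self):
        if not self.dt > 0:
            raise ConfigError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 0:
            raise ConfigError(f"n_steps must be >= 0, got {self.n_steps}")


@dataclass(frozen=True)
class NeuronState:
    """Membrane potential plus the auxiliary variables any model may carry.

    ``w`` is the adaptation current (AdEx, IF-SFA), ``u`` the Izhikevich
    recovery variable, ``s``/``r`` the SRM synaptic and refractory-response
    variables, and ``n``/``m``/``h`` the Hodgkin-Huxley gating variables
    (clamped to [0, 1] after every update).  Fields may be scalars or
    equal-shaped arrays.
    """

    V: Array
    w: Array = 0.0
    u: Array = 0.0
    s: Array = 0.0
    r: Array = 0.0
    n: Array = 0.0
    m: Array = 0.0
    h: Array = 0.0
    refractory_remaining: Array = 0
    t_index: int = 0


def _is_scalar(x: Array) -> bool:
    return np.ndim(x) == 0


def _require_finite(V: Array, I: Array) -> None:
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(I))):
        raise NumericalOverflowError("non-finite membrane potential or input current")


def _out(x, scalar: bool) -> Array:
    return float(x) if scalar else np.asarray(x, dtype=float)


def _out_bool(x, scalar: bool):
    return bool(x) if scalar else np.asarray(x, dtype=bool)


def _out_int(x, scalar: bool):
    return int(x) if scalar else np.asarray(x, dtype=np.int64)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


def _positive(name: str, value) -> None:
    if value is not None and not value > 0:
        raise ConfigError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire: a leaky capacitor with threshold/reset."""

    tau: float
    V_th: float
    V_reset: float
    V_init: float
    R_m: float | None = None      # variant B
    g_leak: float | None = None   # variant B

    def __post_init__(self):
        _positive("tau", self.tau)
        _positive("g_leak", self.g_leak)


@dataclass(frozen=True)
class NLIFParams:
    """Non-linear LIF: post-integration map with spike gain alpha and
    subthreshold leak multiplier beta (variant A), or a quadratic membrane
    term (variant B)."""

    tau: float
    V_th: float
    V_reset: float
    V_init: float
    alpha: float = 0.0
    beta: float = 1.0
    R_m: float | None = None
    g_leak: float | None = None

    def __post_init__(self):
        _positive("tau", self.tau)
        _positive("g_leak", self.g_leak)
        if not 0.0 <= self.beta <= 1.0:
            raise ConfigError(f"beta must be in [0, 1], got {self.beta}")
        if self.alpha < 0:
            raise ConfigError(f"alpha must be >= 0, got {self.alpha}")


@dataclass(frozen=True)
class AdExParams:
    """Adaptive exponential integrate-and-fire.

    Variant A is the single-variable exponential IF with rheobase ``V_rheo``
    and slope factor ``Delta_T``; variant B adds the adaptation current ``w``
    with subthreshold conductance ``a``, spike increment ``b`` and time
    constant ``tau_w``.
    """

    tau_m: float
    V_reset: float
    V_init: float
    V_rheo: float | None = None
    Delta_T: float | None = None
    V_spike: float | None = None
    V_th: float | None = None     # variant B threshold
    a: float = 0.0
    b: float = 0.0
    tau_w: float | None = None
    R_m: float | None = None
    g_leak: float | None = None

    def __post_init__(self):
        _positive("tau_m", self.tau_m)
        _positive("Delta_T", self.Delta_T)
        _positive("tau_w", self.tau_w)
        _positive("g_leak", self.g_leak)


@dataclass(frozen=True)
class IFSFAParams:
    """Integrate-and-fire with spike-frequency adaptation.

    Variant A: LIF plus a slow adaptation current ``w`` (strength ``A``, time
    constant ``tau_w``, post-spike increment ``b``).  Variant B: an
    Izhikevich-like quadratic membrane with capacitance ``C_m``, sensitivity
    ``K``, peak/reset constants and a floor at the resting potential ``V_r``.
    """

    V_init: float
    # variant A
    tau_m: float | None = None
    tau_w: float | None = None
    A: float | None = None
    V_rest: float | None = None
    V_th: float | None = None
    b: float | None = None
    Delta_T: float | None = None  # printed in the benchmark table; unused by Eqs. A
    # variant B
    C_m: float | None = None
    R_m: float | None = None
    K: float | None = None
    V_r: float | None = None
    a: float | None = None
    V_peak: float | None = None
    c: float | None = None
    d: float | None = None

    def __post_init__(self):
        _positive("tau_m", self.tau_m)
        _positive("tau_w", self.tau_w)
        _positive("C_m", self.C_m)


@dataclass(frozen=True)
class ThetaParams:
    """Theta neuron.  Variant A adds a sinusoidal theta-rhythm current to a
    leaky membrane; variant B is a conductance pull toward a threshold
    potential ``theta``."""

    V_init: float
    # variant A
    tau_m: float | None = None
    V_th: float | None = None
    V_reset: float | None = None
    I_theta_max: float = 0.0
    f_theta: float = 0.0
    phi: float = 0.0
    # variant B
    V_r: float | None = None
    g: float = 0.0
    theta: float | None = None
    tau: float | None = None

    def __post_init__(self):
        _positive("tau_m", self.tau_m)
        _positive("tau", self.tau)
        if self.f_theta < 0:
            raise ConfigError(f"f_theta must be >= 0, got {self.f_theta}")
        if self.g < 0:
            raise ConfigError(f"g must be >= 0, got {self.g}")


@dataclass(frozen=True)
class HHParams:
    """Hodgkin-Huxley squid-axon membrane with Na, K and leak channels.

    The voltage-dependent opening/closing rates use the canonical
    squid-axon forms (the benchmark initial gating values 0.3177 / 0.0529 /
    0.5961 are exactly that system's resting equilibrium at -65 mV).
    """

    g_Na: float
    g_K: float
    g_L: float
    E_Na: float
    E_K: float
    E_L: float
    V_init: float
    V_detect: float
    V_reset: float
    C_m: float = 1.0
    n0: float = 0.3177
    m0: float = 0.0529
    h0: float = 0.5961

    def __post_init__(self):
        for name in ("g_Na", "g_K", "g_L"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        _positive("C_m", self.C_m)
        for name in ("n0", "m0", "h0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class QIFParams:
    """Quadratic integrate-and-fire, three formulations.

    Variant A: conductance drive ``dV = dt/C (g_syn (V_syn - V) + I + noise)``.
    Variant B: ``dV/dt = (-V + C_m I)/tau_ref`` with a refractory hold.
    Variant C: the quadratic rule ``dV/dt = (-V + beta V^2 + I)/tau``.
    """

    V_th: float
    V_reset: float
    V_init: float
    # variant A
    C: float | None = None
    g_syn: float = 0.0
    V_syn: float = 0.0
    noise_scale: float = 0.0
    # variant B
    C_m: float | None = None
    tau_ref: float | None = None
    # variant C
    tau: float | None = None
    beta: float | None = None

    def __post_init__(self):
        _positive("C", self.C)
        _positive("C_m", self.C_m)
        _positive("tau", self.tau)
        _positive("tau_ref", self.tau_ref)


@dataclass(frozen=True)
class IzhParams:
    """Izhikevich two-variable model: membrane ``v`` and recovery ``u``."""

    a: float
    b: float
    c: float
    d: float
    V_peak: float
    U_init: float
    V_init: float
    R_m: float | None = None          # variant B gain
    tau: float | None = None          # variant B time constant
    refractory: float | None = None   # variant B refractory period (time units)

    def __post_init__(self):
        _positive("a", self.a)
        _positive("tau", self.tau)


@dataclass(frozen=True)
class SRMParams:
    """Spike response model: synaptic variable ``s``, refractory-response
    variable ``r`` and a membrane that integrates their weighted sum."""

    tau_s: float
    V_th: float
    V_reset: float
    V_init: float
    tau_r: float | None = None     # refractory-variable time constant (variant A)
    tau: float | None = None
    A: float = 1.0                 # synaptic weight (variant B kernel gain)
    w: float = 1.0                 # self-connection weight for the variant-A sum
    g_L: float | None = None       # variant B periodic leak conductance
    E_s: float | None = None       # variant B synaptic reversal potential
    C_m: float | None = None
    g: float = 0.0                 # variant B input conductance
    tau_ref: float | None = None   # variant B leak period / refractory time

    def __post_init__(self):
        _positive("tau_s", self.tau_s)
        _positive("tau_r", self.tau_r)
        _positive("tau", self.tau)


# ---------------------------------------------------------------------------
# step kernels
# ---------------------------------------------------------------------------


def _check_variant(variant: str, allowed: str) -> None:
    if variant not in allowed:
        raise ConfigError(f"variant must be one of {tuple(allowed)}, got {variant!r}")


def lif_step(state: NeuronState, I: Array, grid: SimulationGrid,
             params: LIFParams, variant: str = "A"):
    """One Euler step of the leaky integrate-and-fire neuron.

    Variant A: ``V <- V + (-V + I)/tau * dt``.
    Variant B: ``V <- V + (-V + R_m*I/g_leak)/tau * dt``.
    Threshold at ``V_th``; on spike the potential is reset to ``V_reset``.
    """
    _check_variant(variant, "AB")
    _require_finite(state.V, I)
    scalar = _is_scalar(state.V)
    V = np.asarray(state.V, dtype=float)
    if variant == "A":
        drive = I
    else:
        drive = params.R_m * np.asarray(I) / params.g_leak
    Vc = V + (-V + drive) / params.tau * grid.dt
    spiked = Vc >= params.V_th
    Vn = np.where(spiked, params.V_reset, Vc)
    new = replace(state, V=_out(Vn, scalar), t_index=state.t_index + 1)
    return new, _out_bool(spiked, scalar)


def nlif_step(state: NeuronState, I: Array, grid: SimulationGrid,
              params: NLIFParams, variant: str = "A"):
    """Non-linear integrate-and-fire step.

    Variant A integrates like the LIF and then applies the post-integration
    map: a spiking potential is sent to ``V_reset + alpha*(V - V_th)``, a
    subthreshold one is multiplied by the leak factor ``beta``.  Variant B
    integrates the quadratic membrane ``(-V + R_m*I/g_leak + V^2)/tau`` and
    resets plainly to ``V_reset`` on a spike.
    """
    _check_variant(variant, "AB")
    _require_finite(state.V, I)
    scalar = _is_scalar(state.V)
    V = np.asarray(state.V, dtype=float)
    if variant == "A":
        Vc = V + (-V + I) / params.tau * grid.dt
        spiked = Vc >= params.V_th
        Vn = np.where(spiked, params.V_reset + params.alpha * (Vc - params.V_th),
                      Vc * params.beta)
    else:
        drive = params.R_m * np.asarray(I) / params.g_leak
        Vc = V + (-V + drive + V ** 2) / params.tau * grid.dt
        spiked = Vc >= params.V_th
        Vn = np.where(spiked, params.V_reset, Vc)
    new = replace(state, V=_out(Vn, scalar), t_index=state.t_index + 1)
    return new, _out_bool(spiked, scalar)


def adex_step(state: NeuronState, I: Array, grid: SimulationGrid,
              params: AdExParams, variant: str = "A"):
    """Adaptive exponential integrate-and-fire step.

    Variant A: ``dV/dt = (-V + tau_m*I - V_rheo + Delta_T*exp((V - V_spike)/
    Delta_T)) / tau_m`` with spike/reset at ``V_spike``.  Variant B couples
    the membrane to an adaptation current ``w`` driven by
    ``a*(V - V_reset)`` and incremented by ``b`` after each spike.

    The exponential term may overflow the floating range for strongly
    suprathreshold states; a non-finite candidate potential is treated as a
    spike (in exponential IF models the divergence *is* the spike).
    """
    _check_variant(variant, "AB")
    _require_finite(state.V, I)
    scalar = _is_scalar(state.V)
    V = np.asarray(state.V, dtype=float)
    w = np.asarray(state.w, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        if variant == "A":
            th = params.V_spike
            dV = (-V + params.tau_m * np.asarray(I) - params.V_rheo
                  + params.Delta_T * np.exp((V - params.V_spike) / params.Delta_T)
                  ) / params.tau_m
            Vc = V + dV * grid.dt
            wc = w
        else:
            th = params.V_th
            drive = params.R_m * np.asarray(I) / params.g_leak
            dV = (-V + drive + w * np.exp((V - params.V_th) / params.tau_m)
                  ) / params.tau_m
            Vc = V + dV * grid.dt
            dw = (params.a * (V - params.V_reset) - w) / params.tau_w
            wc = w + dw * grid.dt
    spiked = (Vc >= th) | ~np.isfinite(Vc)
    Vn = np.where(spiked, params.V_reset, Vc)
    wn = np.where(spiked, wc + params.b, wc) if variant == "B" else wc
    new = replace(state, V=_out(Vn, scalar), w=_out(wn, scalar),
                  t_index=state.t_index + 1)
    return new, _out_bool(spiked, scalar)


def ifsfa_step(state: NeuronState, I: Array, grid: SimulationGrid,
               params: IFSFAParams, variant: str = "A"):
    """Integrate-and-fire with spike-frequency adaptation.

    Variant A first relaxes the adaptation current toward ``A*(V - V_rest)``
    with time constant ``tau_w``, then integrates the membrane with the
    adaptation current subtracted from the input; a spike resets the membrane
    to ``V_rest`` and increments the adaptation current by ``b``.

    Variant B is the quadratic form ``dV/dt = R_m*(0.04 V^2 + 140 - U + I) /
    C_m`` with recovery ``dU/dt = a*(K*(V - V_r) - U)``; a spike (at
    ``V_peak``) resets the membrane to ``c`` and jumps ``U`` by ``d``, and a
    membrane that falls below the resting potential ``V_r`` is floored there.
    """
    _check_variant(variant, "AB")
    _require_finite(state.V, I)
    scalar = _is_scalar(state.V)
    V = np.asarray(state.V, dtype=float)
    if variant == "A":
        w = np.asarray(state.w, dtype=float)
        wc = w + (params.A * (V - params.V_rest) - w) / params.tau_w * grid.dt
        Vc = V + (-V + np.asarray(I) - wc) / params.tau_m * grid.dt
        spiked = Vc >= params.V_th
        Vn = np.where(spiked, params.V_rest, Vc)
        wn = np.where(spiked, wc + params.b, wc)
        new = replace(state, V=_out(Vn, scalar), w=_out(wn, scalar),
                      t_index=state.t_index + 1)
        return new, _out_bool(spiked, scalar)
    U = np.asarray(state.w, dtype=float)
    dV = params.R_m * (0.04 * V ** 2 + 140.0 - U + np.asarray(I)) / params.C_m
    Vc = V + dV * grid.dt
    Uc = U + params.a * (params.K * (V - params.V_r) - U) * grid.dt
    spiked = Vc >= params.V_peak
    Vn = np.where(spiked, params.c, Vc)
    Un = np.where(spiked, Uc + params.d, Uc)
    Vn = np.maximum(Vn, params.V_r)  # stated floor at the resting potential
    new = replace(state, V=_out(Vn, scalar), w=_out(Un, scalar),
                  t_index=state.t_index + 1)
    return new, _out_bool(spiked, scalar)


def theta_step(state: NeuronState, I: Array, grid: SimulationGrid,
               params: ThetaParams, variant: str = "A", t: float | None = None):
    """Theta-neuron step.

    Variant A adds the theta-rhythm current ``I_theta_max * sin(2*pi*f_theta*t
    + phi)`` (evaluated at the absolute time ``t`` of the step) to the input
    of a leaky membrane.  Variant B pulls the membrane toward the threshold
    potential through an input conductance:
    ``dV/dt = (-(V - V_r) + g*(theta - V) + I)/tau``.
    """
    _check_variant(variant, "AB")
    _require_finite(state.V, I)
    scalar = _is_scalar(state.V)
    V = np.asarray(state.V, dtype=float)
    if variant == "A":
        if t is None:
            t = state.t_index * grid.dt
        i_theta = params.I_theta_max * math.sin(
            2.0 * math.pi * params.f_theta * t + params.phi)
        Vc = V + (-V + np.asarray(I) + i_theta) / params.tau_m * grid.dt
        spiked = Vc >= params.V_th
        Vn = np.where(spiked, params.V_reset, Vc)
    else:
        Vc = V + (-(V - params.V_r) + params.g * (params.theta - V)
                  + np.asarray(I)) / params.tau * grid.dt
        spiked = Vc >= params.theta
        Vn = np.where(spiked, params.V_r, Vc)
    new = replace(state, V=_out(Vn, scalar), t_index=state.t_index + 1)
    return new, _out_bool(spiked, scalar)


def _vtrap(x: np.ndarray, scale: float) -> np.ndarray:
    """``x / (1 - exp(-x/scale))`` with the removable singularity at x = 0
    evaluated by its limit value ``scale``."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-9
    safe = np.where(small, 1.0, x)
    out = safe / (1.0 - np.exp(-safe / scale))
    return np.where(small, scale + x / 2.0, out)


def hh_rates(V: Array):
    """Canonical squid-axon gating rate functions (ms^-1), resting at -65 mV."""
    V = np.asarray(V, dtype=float)
    alpha_n = 0.01 * _vtrap(V + 55.0, 10.0)
    beta_n = 0.125 * np.exp(-(V + 65.0) / 80.0)
    alpha_m = 0.1 * _vtrap(V + 40.0, 10.0)
    beta_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
    beta_h = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    return alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h


def hh_step(state: NeuronState, I: Array, grid: SimulationGrid,
            params: HHParams, variant: str = "B"):
    """Hodgkin-Huxley step: advance the three gating variables with the
    canonical rate functions, compute the ionic currents and integrate the
    membrane; gating values are clamped to [0, 1].

    The membrane equation is the standard current balance
    ``C_m dV/dt = I - I_Na - I_K - I_L`` with ``I_x = g_x * gates * (V - E_x)``,
    so the resting state is a stable equilibrium.  A spike is detected at
    ``V >= V_detect`` and the membrane is reset to ``V_reset`` (the gating
    variables are not reset).
    """
    _check_variant(variant, "AB")  # single formulation; either tag accepted
    _require_finite(state.V, I)
    scalar = _is_scalar(state.V)
    V = np.asarray(state.V, dtype=float)
    an, bn, am, bm, ah, bh = hh_rates(V)
    dt = grid.dt
    n = np.clip(state.n + (an * (1.0 - state.n) - bn * state.n) * dt, 0.0, 1.0)
    m = np.clip(state.m + (am * (1.0 - state.m) - bm * state.m) * dt, 0.0, 1.0)
    h = np.clip(state.h + (ah * (1.0 - state.h) - bh * state.h) * dt, 0.0, 1.0)
    i_na = params.g_Na * m ** 3 * h * (V - params.E_Na)
    i_k = params.g_K * n ** 4 * (V - params.E_K)
    i_l = params.g_L * (V - params.E_L)
    Vc = V + (np.asarray(I) - i_na - i_k - i_l) / params.C_m * dt
    spiked = Vc >= params.V_detect
    Vn = np.where(spiked, params.V_reset, Vc)
    new = replace(state, V=_out(Vn, scalar), n=_out(n, scalar),
                  m=_out(m, scalar), h=_out(h, scalar),
                  t_index=state.t_index + 1)
    return new, _out_bool(spiked, scalar)


def qif_step(state: NeuronState, I: Array, grid: SimulationGrid,
             params: QIFParams, variant: str = "C",
             rng: np.random.Generator | None = None):
    """Quadratic integrate-and-fire step (variants A, B, C; see QIFParams).

    Variant B holds the membrane at ``V_reset`` for ``round(tau_ref/dt)``
    steps after each spike.  Variant A draws its noise term from the supplied
    generator (zero noise when none is given).
    """
    _check_variant(variant, "ABC")
    _require_finite(state.V, I)
    scalar = _is_scalar(state.V)
    V = np.asarray(state.V, dtype=float)
    if variant == "A":
        noise = 0.0
        if params.noise_scale and rng is not None:
            noise = params.noise_scale * rng.standard_normal(np.shape(V) or None)
            if scalar:
                noise = float(noise)
        Vc = V + grid.dt / params.C * (
            params.g_syn * (params.V_syn - V) + np.asarray(I) + noise)
        spiked = Vc >= params.V_th
        Vn = np.where(spiked, params.V_reset, Vc)
        new = replace(state, V=_out(Vn, scalar), t_index=state.t_index + 1)
        return new, _out_bool(spiked, scalar)
    if variant == "C":
        Vc = V + (-V + params.beta * V ** 2 + np.asarray(I)) / params.tau * grid.dt
        spiked = Vc >= params.V_th
        Vn = np.where(spiked, params.V_reset, Vc)
        new = replace(state, V=_out(Vn, scalar), t_index=state.t_index + 1)
        return new, _out_bool(spiked, scalar)
    # variant B: Eq.-46 drive with a refractory hold
    ref = np.asarray(state.refractory_remaining)
    in_ref = ref > 0
    Vc = V + (-V + params.C_m * np.asarray(I)) / params.tau_ref * grid.dt
    spiked = (Vc >= params.V_th) & ~in_ref
    ref_steps = int(round(params.tau_ref / grid.dt))
    Vn = np.where(in_ref, params.V_reset, np.where(spiked, params.V_reset, Vc))
    refn = np.where(in_ref, ref - 1, np.where(spiked, ref_steps, 0))
    new = replace(state, V=_out(Vn, scalar),
                  refractory_remaining=_out_int(refn, scalar),
                  t_index=state.t_index + 1)
    return new, _out_bool(spiked, scalar)


def izh_step(state: NeuronState, I: Array, grid: SimulationGrid,
             params: IzhParams, variant: str = "A"):
    """Izhikevich step.

    Variant A: ``dv/dt = 0.04 v^2 + 5v + 140 - u + I`` and
    ``du/dt = a(bv - u)``; a spike at ``v >= V_peak`` resets ``v`` to ``c``
    and jumps ``u`` by ``d``.  Variant B scales ``dv/dt`` by ``R_m/tau`` and
    holds the membrane at ``c`` during the refractory period (the recovery
    variable keeps evolving).
    """
    _check_variant(variant, "AB")
    _require_finite(state.V, I)
    scalar = _is_scalar(state.V)
    v = np.asarray(state.V, dtype=float)
    u = np.asarray(state.u, dtype=float)
    quad = 0.04 * v ** 2 + 5.0 * v + 140.0 - u + np.asarray(I)
    if variant == "A":
        vc = v + quad * grid.dt
        uc = u + params.a * (params.b * v - u) * grid.dt
        spiked = vc >= params.V_peak
        vn = np.where(spiked, params.c, vc)
        un = np.where(spiked, uc + params.d, uc)
        new = replace(state, V=_out(vn, scalar), u=_out(un, scalar),
                      t_index=state.t_index + 1)
        return new, _out_bool(spiked, scalar)
    ref = np.asarray(state.refractory_remaining)
    in_ref = ref > 0
    vc = v + params.R_m * quad / params.tau * grid.dt
    uc = u + params.a * (params.b * v - u) * grid.dt
    spiked = (vc >= params.V_peak) & ~in_ref
    ref_steps = int(round((params.refractory or 0.0) / grid.dt))
    vn = np.where(in_ref, params.c, np.where(spiked, params.c, vc))
    un = np.where(spiked, uc + params.d, uc)
    refn = np.where(in_ref, ref - 1, np.where(spiked, ref_steps, 0))
    new = replace(state, V=_out(vn, scalar), u=_out(un, scalar),
                  refractory_remaining=_out_int(refn, scalar),
                  t_index=state.t_index + 1)
    return new, _out_bool(spiked, scalar)


def srm_step(state: NeuronState, I: Array, grid: SimulationGrid,
             params: SRMParams, variant: str = "A"):
    """Spike response model step.

    Variant A integrates the synaptic variable ``s`` (decay ``tau_s``, fed by
    ``r``), the refractory-response variable ``r`` (decay ``tau_r``) and the
    membrane ``V <- V + (-V - I + w*s)/tau_s * dt`` -- the input current
    enters with the printed negative sign.  On a spike the membrane resets
    and both ``s`` and ``r`` are incremented by 1.

    Variant B drives the membrane with a conductance pull toward the
    threshold, a synaptic current ``s*A*(E_s - V)`` and the input, divided by
    ``tau*C_m``; ``s`` relaxes toward ``A`` times the spike indicator, a leak
    ``g_L*(V_init - V)`` is applied every ``round(tau_ref/dt)`` steps and a
    refractory hold follows each spike.
    """
    _check_variant(variant, "AB")
    _require_finite(state.V, I)
    scalar = _is_scalar(state.V)
    V = np.asarray(state.V, dtype=float)
    s = np.asarray(state.s, dtype=float)
    r = np.asarray(state.r, dtype=float)
    dt = grid.dt
    if variant == "A":
        sc = s + (-s / params.tau_s + r) * dt
        rc = r + (-r / params.tau_r) * dt
        Vc = V + (-V - np.asarray(I) + params.w * s) / params.tau_s * dt
        spiked = Vc >= params.V_th
        Vn = np.where(spiked, params.V_reset, Vc)
        sn = np.where(spiked, sc + 1.0, sc)
        rn = np.where(spiked, rc + 1.0, rc)
        new = replace(state, V=_out(Vn, scalar), s=_out(sn, scalar),
                      r=_out(rn, scalar), t_index=state.t_index + 1)
        return new, _out_bool(spiked, scalar)
    ref = np.asarray(state.refractory_remaining)
    in_ref = ref > 0
    dV = (-(V - params.V_reset) + params.g * (params.V_th - V)
          + s * params.A * (params.E_s - V) + np.asarray(I)
          ) / (params.tau * params.C_m)
    Vc = V + dV * dt
    leak_every = max(1, int(round((params.tau_ref or dt) / dt)))
    if (state.t_index + 1) % leak_every == 0 and params.g_L:
        Vc = Vc + params.g_L * (params.V_init - Vc) * dt
    spiked = (Vc >= params.V_th) & ~in_ref
    sn = s + (-s + params.A * spiked.astype(float)) / params.tau_s * dt
    ref_steps = int(round((params.tau_ref or 0.0) / dt))
    Vn = np.where(in_ref, params.V_reset, np.where(spiked, params.V_reset, Vc))
    refn = np.where(in_ref, ref - 1, np.where(spiked, ref_steps, 0))
    new = replace(state, V=_out(Vn, scalar), s=_out(sn, scalar),
                  refractory_remaining=_out_int(refn, scalar),
                  t_index=state.t_index + 1)
    return new, _out_bool(spiked, scalar)


# ---------------------------------------------------------------------------
# model registry / factory
# ---------------------------------------------------------------------------

MODEL_NAMES = (
    "LIF", "NLIF", "AdEx", "IFSFA", "ThetaNeuron", "HH", "QIF",
    "Izhikevich", "SRM",
)

_ALIASES = {
    "lif": "LIF", "nlif": "NLIF", "adex": "AdEx", "ifsfa": "IFSFA",
    "if-sfa": "IFSFA", "if_sfa": "IFSFA", "thetaneuron": "ThetaNeuron",
    "theta": "ThetaNeuron", "th.nu": "ThetaNeuron", "th.nu.": "ThetaNeuron",
    "hh": "HH", "qif": "QIF", "izhikevich": "Izhikevich", "izh": "Izhikevich",
    "srm": "SRM",
}

#: Plotting amplitude attached to each emitted spike; never used in logic.
SPIKE_AMPLITUDES = {
    "LIF": 1.0, "NLIF": 0.7, "AdEx": 0.9, "HH": 1.0, "IFSFA": 1.0,
    "QIF": 1.0, "ThetaNeuron": 1.0, "Izhikevich": 1.0, "SRM": 1.0,
}

_PARAM_CLASSES = {
    "LIF": LIFParams, "NLIF": NLIFParams, "AdEx": AdExParams,
    "IFSFA": IFSFAParams, "ThetaNeuron": ThetaParams, "HH": HHParams,
    "QIF": QIFParams, "Izhikevich": IzhParams, "SRM": SRMParams,
}

_STEP_FUNCS: dict[str, Callable] = {
    "LIF": lif_step, "NLIF": nlif_step, "AdEx": adex_step,
    "IFSFA": ifsfa_step, "ThetaNeuron": theta_step, "HH": hh_step,
    "QIF": qif_step, "Izhikevich": izh_step, "SRM": srm_step,
}


def canonical_name(name: str) -> str:
    key = name.strip().lower()
    if key not in _ALIASES:
        raise ConfigError(f"unknown model name {name!r}; known: {MODEL_NAMES}")
    return _ALIASES[key]


@dataclass(frozen=True)
class Model:
    """A configured neuron: name, formulation variant, parameters and the
    regime time step.  ``step`` dispatches to the matching kernel."""

    name: str
    variant: str
    params: Any
    dt: float
    amplitude: float = 1.0

    def init_state(self, batch: int | None = None) -> NeuronState:
        p = self.params
        def b(x):
            if batch is None:
                return x
            return np.full(batch, x, dtype=float)
        kw: dict[str, Any] = {"V": b(p.V_init)}
        if self.name == "Izhikevich":
            kw["u"] = b(p.U_init)
        if self.name == "HH":
            kw.update(n=b(p.n0), m=b(p.m0), h=b(p.h0))
        if batch is not None:
            kw["refractory_remaining"] = np.zeros(batch, dtype=np.int64)
        return NeuronState(**kw)

    def step(self, state: NeuronState, I: Array, grid: SimulationGrid | None = None,
             rng: np.random.Generator | None = None):
        grid = grid or SimulationGrid(dt=self.dt)
        fn = _STEP_FUNCS[self.name]
        if self.name == "QIF":
            return fn(state, I, grid, self.params, self.variant, rng=rng)
        return fn(state, I, grid, self.params, self.variant)

    @property
    def refractory_steps(self) -> int:
        p = self.params
        tau_ref = getattr(p, "tau_ref", None) or getattr(p, "refractory", None)
        if tau_ref and self.variant == "B":
            return int(round(tau_ref / self.dt))
        return 0


def make_model(name: str, variant: str | None = None,
               params_source: Union[str, Mapping[str, Any], Any, None] = None,
               **overrides) -> Model:
    """Build a configured model.

    ``params_source`` may be a regime name (``"table2"`` for the trace regime,
    ``"table3"`` for the benchmark regime), a mapping of parameter-field
    overrides, or a ready parameter object.  When a regime is named, the
    variant defaults to the regime's formulation (trace -> B, benchmark -> A,
    except QIF whose benchmark column parameterizes the quadratic variant C).
    Table cells marked "X" are simply absent and never required.
    """
    from . import config  # local import: config depends on this module

    name = canonical_name(name)
    cls = _PARAM_CLASSES[name]

    if isinstance(params_source, str):
        regime = params_source
        values, dt = config.regime_params(name, regime)
        values.update(overrides)
        if variant is None:
            variant = config.regime_variant(name, regime)
    elif isinstance(params_source, Mapping):
        values = dict(params_source)
        values.update(overrides)
        dt = values.pop("dt", 0.1)
    elif params_source is None:
        values = dict(overrides)
        dt = values.pop("dt", 0.1)
    else:  # a ready params object
        if not isinstance(params_source, cls):
            raise ConfigError(
                f"params_source of type {type(params_source).__name__} does not "
                f"match model {name}")
        dt = overrides.pop("dt", 0.1)
        return Model(name=name, variant=variant or "A", params=params_source,
                     dt=dt, amplitude=SPIKE_AMPLITUDES[name])

    valid = {f.name for f in fields(cls)}
    unknown = set(values) - valid
    if unknown:
        raise ConfigError(f"unknown parameter(s) for {name}: {sorted(unknown)}")
    try:
        params = cls(**values)
    except TypeError as exc:
        raise ConfigError(f"incomplete parameters for {name}: {exc}") from exc
    return Model(name=name, variant=variant or "A", params=params, dt=dt,
                 amplitude=SPIKE_AMPLITUDES[name])
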