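"""Independent straight-line scalar re-implementations of every model update.

These are written directly from the update equations in plain Python ``math``,
deliberately sharing no code with the package kernels, and serve as the
arithmetic oracle the kernels are checked against (to 1e-12 on random states).
Each function takes plain floats and returns the updated scalars.
"""

import math


def lif(V, I, dt, tau, V_th, V_reset, variant="A", R_m=None, g_leak=None):
    if variant == "A":
        Vc = V + (-V + I) / tau * dt
    else:
        Vc = V + (-V + R_m * I / g_leak) / tau * dt
    if Vc >= V_th:
        return V_reset, True
    return Vc, False


def nlif(V, I, dt, tau, V_th, V_reset, alpha, beta, variant="A",
         R_m=None, g_leak=None):
    if variant == "A":
        Vc = V + (-V + I) / tau * dt
        if Vc >= V_th:
            return V_reset + alpha * (Vc - V_th), True
        return Vc * beta, False
    Vc = V + (-V + R_m * I / g_leak + V * V) / tau * dt
    if Vc >= V_th:
        return V_reset, True
    return Vc, False


def adex(V, w, I, dt, tau_m, V_reset, variant="A", V_rheo=None, Delta_T=None,
         V_spike=None, V_th=None, a=0.0, b=0.0, tau_w=None,
         R_m=None, g_leak=None):
    if variant == "A":
        dV = (-V + tau_m * I - V_rheo
              + Delta_T * math.exp((V - V_spike) / Delta_T)) / tau_m
        Vc = V + dV * dt
        if not math.isfinite(Vc) or Vc >= V_spike:
            return V_reset, w, True
        return Vc, w, False
    dV = (-V + R_m * I / g_leak + w * math.exp((V - V_th) / tau_m)) / tau_m
    Vc = V + dV * dt
    wc = w + (a * (V - V_reset) - w) / tau_w * dt
    if not math.isfinite(Vc) or Vc >= V_th:
        return V_reset, wc + b, True
    return Vc, wc, False


def ifsfa_a(V, w, I, dt, tau_m, tau_w, A, V_rest, V_th, b):
    wc = w + (A * (V - V_rest) - w) / tau_w * dt
    Vc = V + (-V + I - wc) / tau_m * dt
    if Vc >= V_th:
        return V_rest, wc + b, True
    return Vc, wc, False


def ifsfa_b(V, U, I, dt, R_m, C_m, K, V_r, a, V_peak, c, d):
    Vc = V + R_m * (0.04 * V * V + 140.0 - U + I) / C_m * dt
    Uc = U + a * (K * (V - V_r) - U) * dt
    if Vc >= V_peak:
        Vc, Uc, sp = c, Uc + d, True
    else:
        sp = False
    if Vc < V_r:
        Vc = V_r
    return Vc, Uc, sp


def theta(V, I, dt, variant="A", t=0.0, tau_m=None, V_th=None, V_reset=None,
          I_theta_max=0.0, f_theta=0.0, phi=0.0,
          V_r=None, g=0.0, th=None, tau=None):
    if variant == "A":
        i_theta = I_theta_max * math.sin(2.0 * math.pi * f_theta * t + phi)
        Vc = V + (-V + I + i_theta) / tau_m * dt
        if Vc >= V_th:
            return V_reset, True
        return Vc, False
    Vc = V + (-(V - V_r) + g * (th - V) + I) / tau * dt
    if Vc >= th:
        return V_r, True
    return Vc, False


def _hh_rates(V):
    if abs(V + 55.0) < 1e-9:
        an = 0.01 * (10.0 + (V + 55.0) / 2.0)
    else:
        an = 0.01 * (V + 55.0) / (1.0 - math.exp(-(V + 55.0) / 10.0))
    bn = 0.125 * math.exp(-(V + 65.0) / 80.0)
    if abs(V + 40.0) < 1e-9:
        am = 0.1 * (10.0 + (V + 40.0) / 2.0)
    else:
        am = 0.1 * (V + 40.0) / (1.0 - math.exp(-(V + 40.0) / 10.0))
    bm = 4.0 * math.exp(-(V + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(V + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))
    return an, bn, am, bm, ah, bh


def hh(V, n, m, h, I, dt, g_Na, g_K, g_L, E_Na, E_K, E_L, C_m,
       V_detect, V_reset):
    an, bn, am, bm, ah, bh = _hh_rates(V)
    n2 = min(1.0, max(0.0, n + (an * (1.0 - n) - bn * n) * dt))
    m2 = min(1.0, max(0.0, m + (am * (1.0 - m) - bm * m) * dt))
    h2 = min(1.0, max(0.0, h + (ah * (1.0 - h) - bh * h) * dt))
    i_na = g_Na * m2 ** 3 * h2 * (V - E_Na)
    i_k = g_K * n2 ** 4 * (V - E_K)
    i_l = g_L * (V - E_L)
    Vc = V + (I - i_na - i_k - i_l) / C_m * dt
    if Vc >= V_detect:
        return V_reset, n2, m2, h2, True
    return Vc, n2, m2, h2, False


def qif(V, I, dt, V_th, V_reset, variant="C", ref=0, C=None, g_syn=0.0,
        V_syn=0.0, C_m=None, tau_ref=None, tau=None, beta=None):
    if variant == "A":
        Vc = V + dt / C * (g_syn * (V_syn - V) + I)
        if Vc >= V_th:
            return V_reset, 0, True
        return Vc, 0, False
    if variant == "C":
        Vc = V + (-V + beta * V * V + I) / tau * dt
        if Vc >= V_th:
            return V_reset, 0, True
        return Vc, 0, False
    # variant B with refractory hold
    if ref > 0:
        return V_reset, ref - 1, False
    Vc = V + (-V + C_m * I) / tau_ref * dt
    if Vc >= V_th:
        return V_reset, round(tau_ref / dt), True
    return Vc, 0, False


def izh(v, u, I, dt, a, b, c, d, V_peak, variant="A", ref=0,
        R_m=None, tau=None, refractory=0.0):
    quad = 0.04 * v * v + 5.0 * v + 140.0 - u + I
    uc = u + a * (b * v - u) * dt
    if variant == "A":
        vc = v + quad * dt
        if vc >= V_peak:
            return c, uc + d, 0, True
        return vc, uc, 0, False
    if ref > 0:
        return c, uc, ref - 1, False
    vc = v + R_m * quad / tau * dt
    if vc >= V_peak:
        return c, uc + d, round(refractory / dt), True
    return vc, uc, 0, False


def srm(V, s, r, I, dt, tau_s, V_th, V_reset, variant="A", t_index=0, ref=0,
        tau_r=None, w=1.0, tau=None, A=1.0, g=0.0, g_L=None, E_s=None,
        C_m=None, tau_ref=None, V_init=None):
    if variant == "A":
        sc = s + (-s / tau_s + r) * dt
        rc = r + (-r / tau_r) * dt
        Vc = V + (-V - I + w * s) / tau_s * dt
        if Vc >= V_th:
            return V_reset, sc + 1.0, rc + 1.0, 0, True
        return Vc, sc, rc, 0, False
    dV = (-(V - V_reset) + g * (V_th - V) + s * A * (E_s - V) + I) / (tau * C_m)
    Vc = V + dV * dt
    leak_every = max(1, round(tau_ref / dt))
    if (t_index + 1) % leak_every == 0 and g_L:
        Vc = Vc + g_L * (V_init - Vc) * dt
    if ref > 0:
        sc = s + (-s + 0.0) / tau_s * dt
        return V_reset, sc, r, ref - 1, False
    if Vc >= V_th:
        sc = s + (-s + A * 1.0) / tau_s * dt
        return V_reset, sc, r, round(tau_ref / dt), True
    sc = s + (-s + 0.0) / tau_s * dt
    return Vc, sc, r, 0, False
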