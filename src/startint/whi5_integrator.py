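"""Whi5 as the integrator of Cln3-Cdk1 activity.

Mechanistic model of Start commitment: Cln3-Cdk1 phosphorylates the
transcriptional repressor Whi5 while a phosphatase opposes it,

    saturated phosphatase:   dWhi5P/dt = k1*Cln3 - k2
    linear phosphatase:      dWhi5P/dt = k1*Cln3 - k2*Whi5P

with mass conservation Whi5 + Whi5P = Whi5tot.  G1 starts (t = T0) with
Whi5P = 0; Start fires when nuclear Whi5 = Whi5tot - Whi5P drops below the
critical level Whi5c set by the Cln1/2--SBF positive feedback.  In the
saturated regime integrating the rate equation between T0 and TG1 gives the
integral law

    TG1 - T0 = A / (<Cln3> - Cln3c),   A = (Whi5tot - Whi5c)/k1,
                                       Cln3c = k2/k1,

i.e. G1 length is inversely proportional to the average Cln3 signal above
the critical level.  In the linear regime accumulated phosphorylation decays
with rate k2, giving a memory window of length 1/k2 beyond which the
integration effect is erased.

Cln3 inputs are treated as piecewise-constant between samples, which makes
the kinetics solvable in closed form on every segment: trajectories and
threshold-crossing times are computed exactly rather than on a grid.

A parameterizable multi-site phosphorylation chain with explicit Cln1/2
positive feedback (``simulate_network``) reproduces the qualitative
perturbation predictions of the full Start-network model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .cln3_stochastic import ConcentrationTrace
from .trigger_models import G1Result

__all__ = [
    "IntegratorParams",
    "IntegralLaw",
    "MemoryFit",
    "NetworkParams",
    "constant_trace",
    "simulate_whi5p",
    "tg1_from_integrator",
    "law_from_params",
    "predict_tg1",
    "memory_window",
    "simulate_network",
    "network_effective_law",
]


@dataclass(frozen=True)
class IntegratorParams:
    """Parameters of the one-site Whi5 phosphorylation model.

    Units are arbitrary but consistent: Cln3 in signal units (counts or
    a.u.), Whi5 pools in Whi5 units, time in minutes.  ``k2`` is a
    zeroth-order rate (Whi5 units/min) in saturated mode and a first-order
    rate (1/min) in linear mode.
    """

    k1: float = 0.05
    k2: float = 0.75
    whi5_tot: float = 100.0
    whi5_c: float = 40.0
    t0: float = 5.0
    mode: Literal["saturated", "linear"] = "saturated"

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")
        if not 0 <= self.whi5_c < self.whi5_tot:
            raise ValueError("need 0 <= whi5_c < whi5_tot")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")
        if self.mode not in ("saturated", "linear"):
            raise ValueError("mode must be 'saturated' or 'linear'")


@dataclass(frozen=True)
class IntegralLaw:
    """The triple (A, Cln3c, T0) of TG1 - T0 = A / (<Cln3> - Cln3c)."""

    integral_a: float
    cln3_c: float
    t0: float

    def __post_init__(self) -> None:
        if self.integral_a < 0 or self.cln3_c < 0:
            raise ValueError("integral_a and cln3_c must be >= 0")


@dataclass(frozen=True)
class MemoryFit:
    """Result of fitting Whi5(t) = plateau - amplitude * exp(-t/tau)."""

    plateau: float
    amplitude: float
    tau: float
    rss: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def constant_trace(value: float, t_max: float, dt: float = 1.0) -> ConcentrationTrace:
    """Constant Cln3 signal on a regular grid (convenience for closed forms)."""
    times = np.arange(0.0, t_max + 0.5 * dt, dt)
    return ConcentrationTrace(times=times, values=np.full_like(times, float(value)))


def _segments_from(cln3: ConcentrationTrace, t0: float):
    """Piecewise-constant (start, value) segments of the input on [t0, end]."""
    times = np.asarray(cln3.times, dtype=float)
    values = np.asarray(cln3.values, dtype=float)
    if times[-1] <= t0:
        raise ValueError("Cln3 trace must extend beyond t0")
    idx = np.searchsorted(times, t0, side="right") - 1
    idx = max(idx, 0)
    seg_t = np.concatenate([[t0], times[idx + 1:]])
    seg_v = values[idx:]
    return seg_t, seg_v, float(times[-1])


def _advance_saturated(w0, c, p, dt):
    """Closed-form Whi5P after dt of constant Cln3 c (saturated mode)."""
    s = p.k1 * c - p.k2
    w = w0 + s * dt
    return min(max(w, 0.0), p.whi5_tot)


def _advance_linear(w0, c, p, dt):
    w_inf = p.k1 * c / p.k2
    w = w_inf + (w0 - w_inf) * math.exp(-p.k2 * dt)
    return min(max(w, 0.0), p.whi5_tot)


def _crossing_saturated(w0, c, p, dt, target):
    """Time within (0, dt] at which Whi5P reaches target, or None."""
    s = p.k1 * c - p.k2
    if s <= 0 or w0 + s * dt < target:
        return None
    return (target - w0) / s


def _crossing_linear(w0, c, p, dt, target):
    w_inf = p.k1 * c / p.k2
    if w_inf <= target or w0 >= target:
        return 0.0 if w0 >= target else None
    t_star = -math.log((w_inf - target) / (w_inf - w0)) / p.k2
    return t_star if t_star <= dt else None


def simulate_whi5p(
    cln3: ConcentrationTrace, p: IntegratorParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the phosphorylation kinetics along a Cln3 trace.

    Starts from Whi5P(T0) = 0 and treats the Cln3 input as piecewise
    constant, so each segment is solved in closed form (linear or
    exponential relaxation).  Whi5P is clamped to [0, whi5_tot]; the model
    is undefined before T0.

    Returns ``(times, whi5p, whi5_nuclear)`` on the input grid restricted
    to t >= T0, with nuclear Whi5 = whi5_tot - Whi5P.
    """
    seg_t, seg_v, t_end = _segments_from(cln3, p.t0)
    advance = _advance_saturated if p.mode == "saturated" else _advance_linear
    times = [seg_t[0]]
    whi5p = [0.0]
    w = 0.0
    for i, c in enumerate(seg_v):
        t_start = seg_t[i]
        t_stop = seg_t[i + 1] if i + 1 < len(seg_t) else t_end
        if t_stop <= t_start:
            continue
        w = advance(w, c, p, t_stop - t_start)
        times.append(t_stop)
        whi5p.append(w)
    times = np.asarray(times)
    whi5p = np.asarray(whi5p)
    return times, whi5p, p.whi5_tot - whi5p


def tg1_from_integrator(cln3: ConcentrationTrace, p: IntegratorParams) -> G1Result:
    """First time t >= T0 at which nuclear Whi5 drops to whi5_c.

    Equivalent to first-passage of the signed Cln3 integral: Start fires
    when ∫(Cln3 - k2/k1) dt reaches (whi5_tot - whi5_c)/k1.  The crossing
    time is solved in closed form inside the crossing segment.
    """
    target = p.whi5_tot - p.whi5_c
    seg_t, seg_v, t_end = _segments_from(cln3, p.t0)
    advance = _advance_saturated if p.mode == "saturated" else _advance_linear
    crossing = _crossing_saturated if p.mode == "saturated" else _crossing_linear
    w = 0.0
    for i, c in enumerate(seg_v):
        t_start = seg_t[i]
        t_stop = seg_t[i + 1] if i + 1 < len(seg_t) else t_end
        dt = t_stop - t_start
        if dt <= 0:
            continue
        t_star = crossing(w, c, p, dt, target)
        if t_star is not None:
            return G1Result(tg1=float(t_start + t_star), censored=False)
        w = advance(w, c, p, dt)
    return G1Result(tg1=t_end, censored=True)


def law_from_params(p: IntegratorParams) -> IntegralLaw:
    """Map the kinetic constants to the integral-law triple.

    A = (whi5_tot - whi5_c)/k1 and Cln3c = k2/k1; exact for the saturated
    mode, and the k2 -> 0 limit of the linear mode.
    """
    return IntegralLaw(
        integral_a=(p.whi5_tot - p.whi5_c) / p.k1,
        cln3_c=p.k2 / p.k1,
        t0=p.t0,
    )


def predict_tg1(law: IntegralLaw, mean_cln3: float) -> float:
    """G1 length predicted by the inverse law, T0 + A/(<Cln3> - Cln3c)."""
    if mean_cln3 <= law.cln3_c:
        raise ValueError(
            f"mean Cln3 {mean_cln3} <= critical level {law.cln3_c}: never passes Start"
        )
    return law.t0 + law.integral_a / (mean_cln3 - law.cln3_c)


def memory_window(p: IntegratorParams) -> float:
    """Memory length 1/k2 of the linear-phosphatase regime (minutes)."""
    if p.mode != "linear":
        raise ValueError("memory is infinite in saturated mode")
    return 1.0 / p.k2


# ---------------------------------------------------------------------------
# Multi-site Start-network model (stand-in with explicit positive feedback)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkParams:
    """Multi-site Whi5 phosphorylation chain with Cln1/2 positive feedback.

    Whi5 occupies states 0..n_sites by phosphorylation count; every state
    except the fully phosphorylated one is nuclear.  Each site is
    phosphorylated at rate k1_site * (Cln3 + Cln12) and dephosphorylated at
    rate k2_site.  Cln1/2 production is autocatalytic and repressed by
    nuclear Whi5 through a decreasing Hill function (the SBF de-repression
    switch, midpoint ``whi5_c``, sharpness ``hill``):

        dCln12/dt = beta + feedback_strength * Cln12 * act(nuc) - delta * Cln12

    with act(nuc) = 1/(1 + (nuc/whi5_c)^hill).  The loop ignites — net
    Cln1/2 growth turns positive — once nuclear Whi5 falls below the level
    where feedback_strength * act = delta, so the nuclear-Whi5 level at
    commitment (the effective Whi5c) is an *output* of the loop gain, not a
    fixed input.  Start is the first time Cln1/2 exceeds ``cln12_start``.
    Every constant is a configuration knob so a fully specified network can
    be dropped in.
    """

    n_sites: int = 4
    k1_site: float = 0.02
    k2_site: float = 0.5
    feedback_strength: float = 2.0
    hill: float = 4.0
    beta: float = 0.5
    delta: float = 0.35
    whi5_tot: float = 100.0
    whi5_c: float = 40.0
    cln12_start: float = 30.0
    t0: float = 5.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in ("k1_site", "k2_site", "feedback_strength", "hill",
                     "beta", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.whi5_c < self.whi5_tot:
            raise ValueError("need 0 <= whi5_c < whi5_tot")
        if self.cln12_start <= 0:
            raise ValueError("cln12_start must be positive")


def simulate_network(
    params: NetworkParams,
    cln3: ConcentrationTrace | float,
    t_max: float = 300.0,
) -> dict:
    """Integrate the multi-site network and report Start timing.

    Returns a dict with the trajectory (``times``, ``whi5_states``,
    ``whi5_nuclear``, ``cln12``) and the Start result (first crossing of
    Cln1/2 above cln12_start, located by event detection on the dense
    output).
    """
    if isinstance(cln3, ConcentrationTrace):
        cln3_at = lambda t: float(np.interp(t, cln3.times, cln3.values))
        t_end = min(t_max, float(cln3.times[-1]))
    else:
        level = float(cln3)
        cln3_at = lambda t: level
        t_end = t_max
    n = params.n_sites

    def rhs(t, y):
        w = y[: n + 1]
        cln12 = y[n + 1]
        nuc = params.whi5_tot - w[n]
        kp = params.k1_site * (cln3_at(t) + cln12)
        dw = np.zeros(n + 1)
        for i in range(n):
            flux = kp * w[i] - params.k2_site * w[i + 1]
            dw[i] -= flux
            dw[i + 1] += flux
        act = 1.0 / (1.0 + (max(nuc, 0.0) / params.whi5_c) ** params.hill)
        dcln12 = (
            params.beta
            + params.feedback_strength * cln12 * act
            - params.delta * cln12
        )
        return np.append(dw, dcln12)

    def start_event(t, y):
        return y[n + 1] - params.cln12_start

    start_event.terminal = True
    start_event.direction = 1

    y0 = np.zeros(n + 2)
    y0[0] = params.whi5_tot
    sol = solve_ivp(
        rhs,
        (params.t0, t_end),
        y0,
        method="LSODA",
        events=start_event,
        rtol=1e-8,
        atol=1e-10,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"network integration failed: {sol.message}")
    if sol.t_events[0].size:
        result = G1Result(tg1=float(sol.t_events[0][0]), censored=False)
    else:
        result = G1Result(tg1=t_end, censored=True)
    return {
        "times": sol.t,
        "whi5_states": sol.y[: n + 1],
        "whi5_nuclear": params.whi5_tot - sol.y[n],
        "cln12": sol.y[n + 1],
        "g1": result,
    }


def network_effective_law(
    params: NetworkParams,
    cln3_levels: np.ndarray | list[float] | None = None,
    t_max: float = 300.0,
) -> IntegralLaw:
    """Effective (A, Cln3c) of the network, by fitting the inverse law.

    Simulates Start timing for a range of constant Cln3 inputs and fits
    TG1 = T0 + A/(Cln3 - Cln3c) with T0 fixed at the network's t0.
    """
    if cln3_levels is None:
        cln3_levels = np.array(
            [30.0, 35.0, 40.0, 50.0, 60.0, 80.0, 110.0, 150.0, 220.0, 320.0, 480.0]
        )
    levels, tg1 = [], []
    for c in np.asarray(cln3_levels, dtype=float):
        g1 = simulate_network(params, c, t_max=t_max)["g1"]
        if not g1.censored:
            levels.append(c)
            tg1.append(g1.tg1)
    if len(levels) < 3:
        raise RuntimeError("too few uncensored Start events to fit the law")
    levels = np.asarray(levels)
    tg1 = np.asarray(tg1)

    def law(c, a, cc):
        return params.t0 + a / (c - cc)

    a0 = (tg1[0] - params.t0) * (levels[0] - 0.9 * levels.min())
    popt, _ = curve_fit(
        law, levels, tg1, p0=[max(a0, 1.0), 0.5 * levels.min()],
        bounds=([0.0, 0.0], [np.inf, levels.min() - 1e-6]), maxfev=20000,
    )
    return IntegralLaw(integral_a=float(popt[0]), cln3_c=float(popt[1]), t0=params.t0)
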