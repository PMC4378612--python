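"""Exact stochastic simulation of CLN3 mRNA and protein copy numbers.

The Cln3 signal is modelled by a two-stage birth--death process

    mRNA:    synthesis at rate ``a1`` (reduced to ``r * a1`` during early-G1
             suppression), first-order decay ``D1 * m``
    protein: translation at rate ``a2 * exp(alpha * t) * m`` (the exponential
             factor represents ribosome number growing with cell volume),
             first-order decay ``D2 * p``

simulated exactly with a thinning (rejection) variant of the Gillespie
algorithm that handles the time-dependent translation propensity.  The base
model works in molecule counts with a constant nuclear volume; an optional
growing-nucleus variant converts counts to nanomolar concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "AVOGADRO",
    "Cln3KineticParams",
    "MoleculeTrace",
    "NuclearVolumeSpec",
    "ExtrinsicNoiseSpec",
    "ConcentrationTrace",
    "int_round",
    "initial_state",
    "ssa_simulate",
    "sample_extrinsic",
    "to_concentration",
]

AVOGADRO = 6.02214076e23  # mol^-1

#: Maximum look-ahead (min) for the thinning bound on the time-varying
#: translation propensity.  alpha is slow (doubling time ~90 min) so over one
#: minute the propensity changes by <1%; the bound stays tight and the
#: simulation remains exact for any positive value.
_THINNING_STEP = 1.0


@dataclass(frozen=True)
class Cln3KineticParams:
    """Kinetic constants of the Cln3 expression model.

    Defaults satisfy the documented biological constraints: a few mRNA
    copies at steady state, 100-200 protein copies, half-lives of a few
    minutes for both species, and exponential volume growth at a ~90 min
    doubling time.

    Parameters
    ----------
    a1 : mRNA synthesis rate (molecules/min).
    D1 : mRNA degradation rate (1/min).
    a2 : translation rate per mRNA at t=0 (proteins/mRNA/min).
    D2 : protein degradation rate (1/min).
    alpha : exponential growth rate of cell volume (1/min); scales the
        translation propensity as exp(alpha*t).
    r : early-G1 transcriptional capacity ratio in (0, 1], mimicking the
        Ace2 suppression of CLN3 in daughter cells.
    r_duration : duration (min) of the early-G1 suppression.  With the
        default 0, r only sets the suppressed initial state.
    """

    a1: float = 0.693
    D1: float = 0.231
    a2: float = 10.0
    D2: float = 0.231
    alpha: float = 0.0115
    r: float = 0.4
    r_duration: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a1", "D1", "a2", "D2", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.r <= 1:
            raise ValueError("r must satisfy 0 < r <= 1")
        if self.r_duration < 0:
            raise ValueError("r_duration must be >= 0")

    def rate_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in fields(self))


@dataclass(frozen=True)
class MoleculeTrace:
    """Event-time series of mRNA and protein copy numbers.

    ``event_times`` holds the initial time 0 followed by every reaction
    time; counts are piecewise constant between events (left-continuous
    value ``counts[i]`` on ``[event_times[i], event_times[i+1])``).
    """

    event_times: np.ndarray
    mrna_counts: np.ndarray
    protein_counts: np.ndarray
    t_max: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) < 0):
            raise ValueError("event_times must be nondecreasing")
        if np.any(self.mrna_counts < 0) or np.any(self.protein_counts < 0):
            raise ValueError("copy numbers must be nonnegative")

    def protein_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Piecewise-constant protein count at arbitrary times."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return self.protein_counts[np.clip(idx, 0, len(self.protein_counts) - 1)]

    def protein_integral(self) -> np.ndarray:
        """Cumulative ∫ protein dt at each event time (exact, piecewise)."""
        dt = np.diff(self.event_times)
        seg = self.protein_counts[:-1] * dt
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass(frozen=True)
class NuclearVolumeSpec:
    """Nuclear volume model for the count -> concentration conversion.

    The base model assumes a constant nucleus so counts track concentration;
    the growing-nucleus variant sets ``proportional_to_cell`` and lets the
    volume grow as v0 * exp(alpha * t) from the measured 2.9 fL.
    """

    v0: float = 2.9  # fL
    proportional_to_cell: bool = False
    alpha: float = 0.0115  # 1/min, shared with Cln3KineticParams

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ValueError("v0 must be positive")

    def volume_at(self, t: np.ndarray | float) -> np.ndarray | float:
        if self.proportional_to_cell:
            return self.v0 * np.exp(self.alpha * np.asarray(t, dtype=float))
        return self.v0 * np.ones_like(np.asarray(t, dtype=float))


@dataclass(frozen=True)
class ExtrinsicNoiseSpec:
    """Cell-to-cell parameter variability.

    Each targeted parameter is drawn independently per cell from a normal
    distribution centred on its nominal value with sd = cv * nominal,
    truncated (by redraw) to the parameter's valid range.
    """

    cv: float = 0.2
    targets: frozenset[str] = field(
        default_factory=lambda: frozenset({"a1", "D1", "a2", "D2", "alpha", "r"})
    )

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


@dataclass(frozen=True)
class ConcentrationTrace:
    """Cln3 signal resampled onto a regular grid (counts or nM)."""

    times: np.ndarray
    values: np.ndarray
    units: str = "molecules"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be nonnegative")


def int_round(x: float) -> int:
    """Nearest-integer rounding, ties away from zero (Int(x) rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def initial_state(params: Cln3KineticParams) -> tuple[int, int]:
    """Suppressed deterministic steady state, rounded to integers.

    mRNA0 = Int(a1/D1 * r), protein0 = Int(a1*a2/(D1*D2) * r): the fixed
    point of the rate equations with transcription at the early-G1 capacity
    ``r``.
    """
    mrna0 = int_round(params.a1 / params.D1 * params.r)
    protein0 = int_round(params.a1 * params.a2 / (params.D1 * params.D2) * params.r)
    return mrna0, protein0


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class _UniformBuffer:
    """Buffered scalar uniforms from a Generator (fast inner-loop draws)."""

    __slots__ = ("rng", "buf", "i")

    def __init__(self, rng: np.random.Generator, size: int = 8192):
        self.rng = rng
        self.buf = rng.random(size)
        self.i = 0

    def next(self) -> float:
        if self.i >= len(self.buf):
            self.buf = self.rng.random(len(self.buf))
            self.i = 0
        u = self.buf[self.i]
        self.i += 1
        return u


def ssa_simulate(
    params: Cln3KineticParams,
    t_max: float,
    seed,
    *,
    t_start: float = 0.0,
    initial: tuple[int, int] | None = None,
    stop_protein: float | None = None,
    stop_integral: float | None = None,
    max_events: int = 50_000_000,
) -> MoleculeTrace:
    """Exact SSA realization of the Cln3 expression model on [0, t_max].

    The time-dependent translation propensity ``a2*exp(alpha*t)*m`` is
    handled by thinning: candidate events are generated from an upper bound
    refreshed at least every minute and accepted with probability equal to
    the true total propensity at the candidate time, which is exact for
    monotone rates.

    Parameters
    ----------
    t_start, initial : continuation support — start the realization at
        ``t_start`` from state ``initial = (mrna, protein)`` instead of
        time 0 and the suppressed steady state.  Chaining segments with the
        same Generator reproduces one statistically seamless trajectory.
    stop_protein, stop_integral : optional early-stop levels.  When both are
        given, simulation halts once the protein count has reached
        ``stop_protein`` *and* the running ∫protein dt has reached
        ``stop_integral`` (the trace up to that point is unaffected; this
        only avoids simulating beyond the last first-passage of interest).
    seed : int, SeedSequence or Generator; identical seeds give identical
        traces.
    """
    if t_max <= t_start:
        raise ValueError("t_max must exceed t_start")
    rng = _as_generator(seed)
    uni = _UniformBuffer(rng)

    a1, D1, a2, D2 = params.a1, params.D1, params.a2, params.D2
    alpha, r, r_dur = params.alpha, params.r, params.r_duration
    m, p = initial_state(params) if initial is None else initial

    check_stop = stop_protein is not None and stop_integral is not None
    integral = 0.0

    times = [t_start]
    mrna = [m]
    prot = [p]
    t = t_start
    n_events = 0
    exp = math.exp
    log = math.log

    while t < t_max:
        lam1 = a1 * r if t < r_dur else a1
        lam2 = D1 * m
        lam4 = D2 * p
        # look-ahead window: capped step, never straddling the r_dur switch
        step = _THINNING_STEP
        if t < r_dur:
            step = min(step, r_dur - t)
        step = min(step, t_max - t)
        lam3_bound = a2 * exp(alpha * (t + step)) * m
        bound = lam1 + lam2 + lam3_bound + lam4
        if bound <= 0.0:
            # absorbing state (m = p = 0 and a1 impossible; defensive)
            t += step
            continue
        if not math.isfinite(bound) or bound > 1e12:
            raise FloatingPointError(
                f"event rate exploded (bound={bound:.3g} at t={t:.3g} min); "
                "alpha is too large for this horizon"
            )
        wait = -log(1.0 - uni.next()) / bound
        if wait > step:
            if check_stop:
                integral += p * step
            t += step
            continue
        if check_stop:
            integral += p * wait
        t += wait
        lam3 = a2 * exp(alpha * t) * m
        v = uni.next() * bound
        if v < lam1:
            m += 1
        elif v < lam1 + lam2:
            m -= 1
        elif v < lam1 + lam2 + lam3:
            p += 1
        elif v < lam1 + lam2 + lam3 + lam4:
            p -= 1
        else:
            continue  # thinned candidate: time advances, no reaction
        times.append(t)
        mrna.append(m)
        prot.append(p)
        n_events += 1
        if check_stop and p >= stop_protein and integral >= stop_integral:
            break
        if n_events >= max_events:
            raise FloatingPointError("event budget exhausted; rates too high")

    return MoleculeTrace(
        event_times=np.asarray(times),
        mrna_counts=np.asarray(mrna, dtype=np.int64),
        protein_counts=np.asarray(prot, dtype=np.int64),
        t_max=float(t_max),
    )


def _truncated_normal(rng, nominal: float, cv: float, lo: float, hi: float) -> float:
    """Normal(nominal, cv*nominal) truncated to (lo, hi] by redraw."""
    if cv == 0:
        return nominal
    sd = cv * abs(nominal)
    for _ in range(1000):
        x = rng.normal(nominal, sd)
        if lo < x <= hi:
            return x
    raise RuntimeError("truncated-normal sampling failed to land in range")


def sample_extrinsic(
    params: Cln3KineticParams,
    thresholds: list[float],
    spec: ExtrinsicNoiseSpec,
    seed,
) -> tuple[Cln3KineticParams, list[float]]:
    """Draw one cell's parameter set under extrinsic noise.

    Every kinetic parameter named in ``spec.targets`` and every entry of
    ``thresholds`` is independently perturbed with relative dispersion
    ``spec.cv``; rates stay positive and ``r`` stays in (0, 1].
    """
    rng = _as_generator(seed)
    updates = {}
    for name in params.rate_names():
        if name not in spec.targets:
            continue
        nominal = getattr(params, name)
        hi = 1.0 if name == "r" else math.inf
        updates[name] = _truncated_normal(rng, nominal, spec.cv, 0.0, hi)
    new_thresholds = [
        _truncated_normal(rng, th, spec.cv, 0.0, math.inf) for th in thresholds
    ]
    return replace(params, **updates), new_thresholds


def to_concentration(
    trace: MoleculeTrace,
    vol: NuclearVolumeSpec | None = None,
    grid_dt: float = 1.0,
    *,
    convert_units: bool = True,
) -> ConcentrationTrace:
    """Resample an event trace onto a regular grid, optionally in nM.

    With ``vol=None`` or ``convert_units=False`` the values are raw counts
    (the base-model convention that a constant nucleus makes abundance track
    concentration).  Otherwise concentration = count / (N_A * V(t)) with V
    in liters, reported in nM.
    """
    if grid_dt <= 0:
        raise ValueError("grid_dt must be positive")
    times = np.arange(0.0, trace.t_max + 0.5 * grid_dt, grid_dt)
    times = times[times <= trace.t_max]
    counts = np.asarray(trace.protein_at(times), dtype=float)
    if vol is None or not convert_units:
        return ConcentrationTrace(times=times, values=counts, units="molecules")
    v_liters = np.asarray(vol.volume_at(times)) * 1e-15
    nM = counts / (AVOGADRO * v_liters) * 1e9
    return ConcentrationTrace(times=times, values=nM, units="nM")
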