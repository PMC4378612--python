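"""Competing Start-trigger rules and their first-passage G1 lengths.

Two hypotheses for how the noisy Cln3 signal commits a cell to division:

* **Instantaneous Model** — Start fires the first time the Cln3 level
  itself exceeds a threshold.
* **Integration Model** — Start fires the first time the running integral
  of the Cln3 level exceeds a threshold.

Both are evaluated exactly on piecewise-constant event traces, so results
do not depend on any sampling grid.  The module also provides ensemble
statistics of the G1 length TG1, threshold calibration to a target mean,
and the peak-coincidence test that probes whether Start co-occurs with the
Cln3 maximum (as the Instantaneous Model requires).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .cln3_stochastic import (
    Cln3KineticParams,
    ConcentrationTrace,
    ExtrinsicNoiseSpec,
    MoleculeTrace,
    NuclearVolumeSpec,
    ssa_simulate,
    sample_extrinsic,
    to_concentration,
)

__all__ = [
    "TriggerSpec",
    "G1Result",
    "DistributionSummary",
    "first_passage_instantaneous",
    "first_passage_integration",
    "first_passage",
    "tg1_ensemble",
    "calibrate_threshold",
    "peak_coincidence_test",
]


@dataclass(frozen=True)
class TriggerSpec:
    """A trigger rule: which model, its threshold, and integration options.

    ``threshold`` is in molecules (instantaneous) or molecules*min
    (integration); nM / nM*min in the growing-nucleus variant.  ``baseline``
    is a critical-level offset subtracted from the signal before
    integration; with ``signed_integrand`` the difference may go negative
    (accumulated phosphorylation being undone), otherwise it is clipped
    at zero.
    """

    model: Literal["instantaneous", "integration"]
    threshold: float
    baseline: float = 0.0
    signed_integrand: bool = True

    def __post_init__(self) -> None:
        if self.model not in ("instantaneous", "integration"):
            raise ValueError("model must be 'instantaneous' or 'integration'")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")


@dataclass(frozen=True)
class G1Result:
    """First-passage time TG1, with censoring when never triggered."""

    tg1: float
    censored: bool = False

    def __post_init__(self) -> None:
        if self.tg1 < 0:
            raise ValueError("tg1 must be >= 0")


@dataclass(frozen=True)
class DistributionSummary:
    n: int
    mean: float
    sd: float
    cv: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    censored_fraction: float


def _signal_segments(trace) -> tuple[np.ndarray, np.ndarray, float]:
    """(times, values, t_max) with values piecewise-constant from times[i]."""
    if isinstance(trace, MoleculeTrace):
        return trace.event_times, trace.protein_counts.astype(float), trace.t_max
    if isinstance(trace, ConcentrationTrace):
        return trace.times, trace.values, float(trace.times[-1])
    raise TypeError("trace must be MoleculeTrace or ConcentrationTrace")


def first_passage_instantaneous(trace, spec: TriggerSpec, t_max: float | None = None) -> G1Result:
    """Smallest t with signal(t) >= threshold; censored if never reached."""
    if spec.model != "instantaneous":
        raise ValueError("spec.model must be 'instantaneous'")
    times, values, trace_tmax = _signal_segments(trace)
    horizon = trace_tmax if t_max is None else t_max
    hit = np.nonzero((values >= spec.threshold) & (times <= horizon))[0]
    if len(hit) == 0:
        return G1Result(tg1=horizon, censored=True)
    return G1Result(tg1=float(times[hit[0]]), censored=False)


def first_passage_integration(trace, spec: TriggerSpec, t_max: float | None = None) -> G1Result:
    """Smallest t with ∫0^t (signal - baseline) ds >= threshold.

    The integral is computed exactly on the piecewise-constant trace and
    the crossing time solved within the crossing segment, so the result is
    independent of how finely the trace is sampled.
    """
    if spec.model != "integration":
        raise ValueError("spec.model must be 'integration'")
    times, values, trace_tmax = _signal_segments(trace)
    horizon = trace_tmax if t_max is None else t_max
    integrand = values - spec.baseline
    if not spec.signed_integrand:
        integrand = np.maximum(integrand, 0.0)
    seg_ends = np.append(times[1:], horizon)
    dt = np.clip(seg_ends - times, 0.0, None)
    cum = np.concatenate([[0.0], np.cumsum(integrand * dt)])
    above = np.nonzero(cum[1:] >= spec.threshold)[0]
    if len(above) == 0:
        return G1Result(tg1=horizon, censored=True)
    i = above[0]  # first segment whose end reaches the threshold
    # integrand[i] > 0 is guaranteed at an upward crossing
    t_cross = times[i] + (spec.threshold - cum[i]) / integrand[i]
    return G1Result(tg1=float(t_cross), censored=False)


def first_passage(trace, spec: TriggerSpec, t_max: float | None = None) -> G1Result:
    if spec.model == "instantaneous":
        return first_passage_instantaneous(trace, spec, t_max)
    return first_passage_integration(trace, spec, t_max)


def summarize_tg1(
    tg1: np.ndarray,
    censored: np.ndarray,
    n_bins: int = 30,
) -> DistributionSummary:
    """Summary statistics over the uncensored TG1 values.

    Censored cells are excluded from mean/sd/cv and reported via
    ``censored_fraction``.
    """
    tg1 = np.asarray(tg1, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    ok = tg1[~censored]
    if len(ok) == 0:
        raise ValueError("all cells censored; nothing to summarize")
    mean = float(np.mean(ok))
    sd = float(np.std(ok, ddof=1)) if len(ok) > 1 else 0.0
    counts, edges = np.histogram(ok, bins=n_bins)
    frac = float(np.mean(censored))
    if frac > 0:
        warnings.warn(f"{frac:.1%} of cells censored", stacklevel=2)
    return DistributionSummary(
        n=int(len(tg1)),
        mean=mean,
        sd=sd,
        cv=sd / mean if mean > 0 else float("nan"),
        hist_edges=edges,
        hist_counts=counts,
        censored_fraction=frac,
    )


def tg1_ensemble(
    n_cells: int,
    params: Cln3KineticParams,
    noise: ExtrinsicNoiseSpec | None,
    spec: TriggerSpec,
    seed,
    *,
    volume: NuclearVolumeSpec | None = None,
    t_max: float = 300.0,
    companion: TriggerSpec | None = None,
) -> DistributionSummary | tuple[DistributionSummary, DistributionSummary]:
    """Simulate n_cells traces and summarize the TG1 distribution.

    With extrinsic ``noise``, each cell gets an independent draw of the
    kinetic parameters and of the threshold(s).  ``companion`` lets a second
    trigger rule be evaluated on the *same* traces (the paired comparison
    of the two models on one simulated population); in that case a tuple of
    summaries is returned in (spec, companion) order.

    In the growing-nucleus variant (``volume`` given with
    ``proportional_to_cell``) the event trace is converted to nM on a 0.2-min
    grid before the trigger rules are applied.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    specs = [spec] if companion is None else [spec, companion]
    tg1 = np.empty((len(specs), n_cells))
    cen = np.zeros((len(specs), n_cells), dtype=bool)
    for i in range(n_cells):
        cell_params = params
        thresholds = [s.threshold for s in specs]
        if noise is not None and noise.cv > 0:
            cell_params, thresholds = sample_extrinsic(params, thresholds, noise, rng)
        # early stop once every rule could have fired (conservative in nM mode:
        # concentrations only shrink relative to counts on this scale)
        stop_p = max(
            (th for s, th in zip(specs, thresholds) if s.model == "instantaneous"),
            default=0.0,
        )
        stop_i = max(
            (th + s.baseline * t_max for s, th in zip(specs, thresholds)
             if s.model == "integration"),
            default=0.0,
        )
        if volume is not None:
            # thresholds are in nM; convert the stop levels back to counts
            # using the *initial* (smallest) volume => counts bound is safe
            from .cln3_stochastic import AVOGADRO

            factor = AVOGADRO * volume.v0 * 1e-15 / 1e9  # counts per nM
            stop_p *= factor
            stop_i *= factor * np.exp(volume.alpha * t_max)
        trace = ssa_simulate(
            cell_params, t_max, rng, stop_protein=stop_p, stop_integral=stop_i
        )
        signal = trace
        if volume is not None:
            signal = to_concentration(trace, volume, grid_dt=0.2)
        for j, (s, th) in enumerate(zip(specs, thresholds)):
            cell_spec = TriggerSpec(
                model=s.model, threshold=th, baseline=s.baseline,
                signed_integrand=s.signed_integrand,
            )
            res = first_passage(signal, cell_spec, t_max)
            tg1[j, i] = res.tg1
            cen[j, i] = res.censored
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summaries = [summarize_tg1(tg1[j], cen[j]) for j in range(len(specs))]
    for s in summaries:
        if s.censored_fraction > 0:
            warnings.warn(
                f"{s.censored_fraction:.1%} of cells censored", stacklevel=2
            )
    if companion is None:
        return summaries[0]
    return summaries[0], summaries[1]


def calibrate_threshold(
    model: Literal["instantaneous", "integration"],
    params: Cln3KineticParams,
    target_mean_tg1: float,
    seed,
    *,
    noise: ExtrinsicNoiseSpec | None = None,
    n_cells: int = 500,
    t_max: float = 300.0,
    bracket: tuple[float, float] = (1.0, 1e6),
    tol: float = 0.5,
    max_iter: int = 40,
) -> float:
    """Bisect the threshold until mean TG1 matches a target.

    Uses common random numbers (the same seed for every candidate
    threshold) so the mean is a monotone, noise-free function of the
    threshold and bisection converges.
    """

    def mean_at(th: float) -> float:
        spec = TriggerSpec(model=model, threshold=th)
        try:
            summ = tg1_ensemble(n_cells, params, noise, spec, seed, t_max=t_max)
        except ValueError:
            return t_max  # every cell censored: mean is at least the horizon
        return summ.mean

    lo, hi = bracket
    f_lo, f_hi = mean_at(lo), mean_at(hi)
    if not (f_lo <= target_mean_tg1 <= f_hi):
        raise ValueError(
            f"target mean {target_mean_tg1} not bracketed: "
            f"[{f_lo:.2f}, {f_hi:.2f}] min over thresholds {bracket}"
        )
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)  # geometric bisection: thresholds span decades
        f_mid = mean_at(mid)
        if abs(f_mid - target_mean_tg1) < tol:
            return mid
        if f_mid < target_mean_tg1:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def peak_coincidence_test(
    trace: ConcentrationTrace,
    tg1: float,
    tolerance: float,
) -> tuple[bool, bool]:
    """Does Start coincide with the Cln3 peak, as instantaneous triggering demands?

    Returns ``(passed, peak_exceeds_20pct)``: passed iff the time of the
    trace maximum is within ``tolerance`` minutes of ``tg1``; the flag is
    set iff the peak value exceeds the value at Start by more than 20%.
    A flat trace passes (its peak is everywhere, including at Start).
    """
    if tg1 < trace.times[0] or tg1 > trace.times[-1]:
        raise ValueError("tg1 outside trace support")
    values = trace.values
    i_peak = int(np.argmax(values))
    t_peak = float(trace.times[i_peak])
    v_peak = float(values[i_peak])
    v_start = float(np.interp(tg1, trace.times, values))
    if np.allclose(values, values[0]):
        return True, False
    passed = abs(t_peak - tg1) <= tolerance
    flag = v_peak > 1.2 * v_start
    return passed, flag
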