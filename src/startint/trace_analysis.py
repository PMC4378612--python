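"""Quantification of single-cell fluorescence traces and the inverse-law fit.

Implements the measurement side of the pipeline: spline smoothing of raw
traces, the derivative-based definition of G1 (nuclear Whi5 entry = local
maximum of the first derivative, exit = local minimum), per-cycle
quantification (Whi5tot as the G1 maximum of nuclear Whi5, ⟨Cln3⟩ as the
G1 time-average, integral A as their product with TG1), the exponential
growth-rate fit with its standard-error filter, the memory-length fit
Whi5(t) = A - B*exp(-t/tau), and the binned log-log fit of the inverse law

    log(TG1 - T0) = intercept + slope * log(<Cln3> - Cln3c)

with its selection criteria: T0 fixed per marker (5 min Whi5, 12 min MCM),
Cln3c grid-searched over [min_Cln3 - 200, min_Cln3], points binned by Cln3
intensity, only bins with more than 10 points used, per-bin medians fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .whi5_integrator import MemoryFit

__all__ = [
    "CellTrace",
    "CellCycleRecord",
    "LogLogFit",
    "T0_BY_MARKER",
    "smooth_trace",
    "extract_g1",
    "quantify_cycle",
    "fit_growth_rate",
    "fit_memory_length",
    "fit_loglog",
    "cv",
    "analyze_population",
]

#: Fixed lower asymptote T0 (min) by G1 marker: time from Whi5 nuclear
#: entry to Cdc14 inactivation.  The MCM reporter enters the nucleus 2 min
#: before and exits 5 min after Whi5, hence the larger offset.
T0_BY_MARKER = {"whi5": 5.0, "mcm": 12.0}

FRAME_MIN = 3.0  # imaging cadence (min/frame)


@dataclass
class CellTrace:
    """One cell's fluorescence time course on the 3-min imaging grid."""

    times: np.ndarray
    cln3_signal: np.ndarray
    whi5_nuclear_signal: np.ndarray
    cell_area: np.ndarray | None = None
    lineage: Literal["mother", "daughter"] = "mother"
    condition: str = ""
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cln3_signal = np.asarray(self.cln3_signal, dtype=float)
        self.whi5_nuclear_signal = np.asarray(self.whi5_nuclear_signal, dtype=float)
        n = len(self.times)
        if len(self.cln3_signal) != n or len(self.whi5_nuclear_signal) != n:
            raise ValueError("channel grids must be aligned")
        if np.any(self.cln3_signal < 0) or np.any(self.whi5_nuclear_signal < 0):
            raise ValueError("signals must be nonnegative")


@dataclass(frozen=True)
class CellCycleRecord:
    """Per-cycle quantities entering the population-level fits."""

    tg1: float
    mean_cln3_g1: float
    whi5_tot: float
    integral_a_est: float
    growth_rate: float | None = None
    lineage: str = "mother"
    condition: str = ""
    cell_id: str = ""


@dataclass(frozen=True)
class LogLogFit:
    """Binned log-log fit of the inverse law with its selection metadata."""

    t0_fixed: float
    cln3_c: float
    slope: float
    intercept: float
    r2: float
    bins: pd.DataFrame  # columns: median_cln3, median_tg1, n
    fit_mode: str
    n_records: int


def smooth_trace(
    times: np.ndarray, values: np.ndarray, stiffness: float | None = None
) -> np.ndarray:
    """Penalized smoothing spline of one channel.

    ``stiffness`` is the spline penalty; by default it is chosen by
    generalized cross-validation.  Requires at least 6 points.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 6:
        raise ValueError("trace too short to smooth (need >= 6 points)")
    spl = make_smoothing_spline(times, values, lam=stiffness)
    return spl(times)


def _smoothing_spline(times, values, stiffness=None):
    return make_smoothing_spline(
        np.asarray(times, float), np.asarray(values, float), lam=stiffness
    )


def extract_g1(
    times: np.ndarray,
    whi5_nuclear: np.ndarray,
    stiffness: float | None = None,
    edge_frames: int = 2,
) -> tuple[float, float, float]:
    """G1 window from the first derivative of the smoothed Whi5 signal.

    Nuclear entry is the local maximum of the derivative (signal rising
    fastest) and exit the subsequent local minimum (falling fastest),
    searched on a dense grid restricted to the trace minus ``edge_frames``
    frames at each end.  Returns ``(t_enter, t_exit, tg1)``.

    Raises ``ValueError`` when no qualifying extrema pair exists (e.g. a
    flat or monotone trace), so such records can be rejected and logged.
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 6:
        raise ValueError("trace too short for G1 extraction")
    spl = _smoothing_spline(times, whi5_nuclear, stiffness)
    lo = times[0] + edge_frames * FRAME_MIN
    hi = times[-1] - edge_frames * FRAME_MIN
    if hi <= lo:
        raise ValueError("trace shorter than the search window")
    grid = np.linspace(lo, hi, max(200, len(times) * 20))
    smoothed = spl(grid)
    deriv = spl.derivative()(grid)
    span = float(np.ptp(smoothed))
    scale = max(1.0, float(np.max(np.abs(smoothed))))
    if span <= 1e-9 * scale or np.max(np.abs(deriv)) * (hi - lo) < 0.05 * span:
        raise ValueError("flat trace: no entry/exit extrema")
    i_enter = int(np.argmax(deriv))
    if deriv[i_enter] <= 0:
        raise ValueError("no rising nuclear-entry phase")
    # exit: nuclear export at Start is the LAST strong descent — after it
    # the signal sits at background for the rest of the trace, whereas the
    # gradual integrator discharge and transient noise dips are followed by
    # further signal (and by the export drop itself).  Candidates are local
    # minima of the derivative after entry that are at least a quarter as
    # steep as the steepest descent and whose level drops below half of
    # the G1 peak shortly afterwards.
    floor = float(np.min(smoothed))
    dgrid = grid[1] - grid[0]
    k = max(int(round(2 * FRAME_MIN / dgrid)), 1)
    padded = np.concatenate([smoothed, np.full(k, smoothed[-1])])
    look_min = np.min(
        np.lib.stride_tricks.sliding_window_view(padded, k + 1), axis=1
    )
    run_peak = np.maximum.accumulate(smoothed)
    local_min = np.zeros(len(deriv), dtype=bool)
    local_min[1:-1] = (deriv[1:-1] <= deriv[:-2]) & (deriv[1:-1] <= deriv[2:])
    local_min[-1] = deriv[-1] < deriv[-2]
    steepest = float(np.min(deriv[i_enter + 1 :]))
    candidates = (
        (np.arange(len(grid)) > i_enter)
        & local_min
        & (deriv < 0.25 * steepest)
        & (look_min < floor + 0.5 * (run_peak - floor))
    )
    if steepest >= 0 or not np.any(candidates):
        raise ValueError("no qualifying exit (signal never exported)")
    i_exit = int(np.nonzero(candidates)[0][-1])
    t_enter = float(grid[i_enter])
    t_exit = float(grid[i_exit])
    if t_exit <= t_enter:
        raise ValueError("exit precedes entry")
    return t_enter, t_exit, t_exit - t_enter


def quantify_cycle(trace: CellTrace, g1: tuple[float, float]) -> CellCycleRecord:
    """Per-cycle quantities over the G1 window ``g1 = (t_enter, t_exit)``.

    Whi5tot is the maximum of the nuclear Whi5 signal during G1, ⟨Cln3⟩ the
    time-average (trapezoidal) of the Cln3 signal over G1, and the integral
    A estimate their product with the G1 length.
    """
    t_enter, t_exit = g1
    if t_exit <= t_enter:
        raise ValueError("invalid G1 window")
    tg1 = t_exit - t_enter
    mask = (trace.times >= t_enter) & (trace.times <= t_exit)
    if mask.sum() < 2:
        raise ValueError("G1 window covers fewer than 2 frames")
    t_g1 = trace.times[mask]
    whi5_tot = float(np.max(trace.whi5_nuclear_signal[mask]))
    mean_cln3 = float(np.trapezoid(trace.cln3_signal[mask], t_g1) / (t_g1[-1] - t_g1[0]))
    growth = None
    if trace.cell_area is not None:
        try:
            growth = fit_growth_rate(t_g1, np.asarray(trace.cell_area)[mask])
        except ValueError:
            growth = None
    return CellCycleRecord(
        tg1=tg1,
        mean_cln3_g1=mean_cln3,
        whi5_tot=whi5_tot,
        integral_a_est=tg1 * mean_cln3,
        growth_rate=growth,
        lineage=trace.lineage,
        condition=trace.condition,
        cell_id=trace.cell_id,
    )


def fit_growth_rate(
    times: np.ndarray, area: np.ndarray, max_se: float = 0.02
) -> float:
    """Exponential growth rate from a linear fit of log(area).

    Cells are assumed to grow exponentially in G1; fits with fewer than 7
    points or with a slope standard error >= ``max_se`` are rejected.
    """
    times = np.asarray(times, dtype=float)
    area = np.asarray(area, dtype=float)
    if len(times) <= 6:
        raise ValueError("growth fit needs more than six points")
    if np.any(area <= 0):
        raise ValueError("areas must be positive")
    res = linregress(times, np.log(area))
    if res.stderr >= max_se:
        raise ValueError(f"growth-rate SE {res.stderr:.3g} >= {max_se}")
    return float(res.slope)


def fit_memory_length(
    times: np.ndarray, whi5: np.ndarray, p0: tuple[float, float, float] | None = None
) -> MemoryFit:
    """Fit the Whi5 nuclear-entry recovery Whi5(t) = A - B*exp(-t/tau).

    ``tau`` (the memory length, 1/dephosphorylation rate) is constrained
    positive.  Non-convergence raises ``RuntimeError`` with diagnostics.
    """
    times = np.asarray(times, dtype=float)
    whi5 = np.asarray(whi5, dtype=float)

    def model(t, plateau, amplitude, tau):
        return plateau - amplitude * np.exp(-t / tau)

    if p0 is None:
        plateau0 = float(whi5[-1])
        amp0 = max(float(whi5[-1] - whi5[0]), 1e-6)
        p0 = (plateau0, amp0, max((times[-1] - times[0]) / 3.0, 1.0))
    try:
        popt, _ = curve_fit(
            model, times, whi5, p0=p0,
            bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"memory-length fit did not converge: {err}") from err
    resid = whi5 - model(times, *popt)
    return MemoryFit(
        plateau=float(popt[0]),
        amplitude=float(popt[1]),
        tau=float(popt[2]),
        rss=float(np.sum(resid**2)),
    )


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation sd/mean of a sample (mean must be > 0)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    mean = float(np.mean(arr))
    if mean <= 0:
        raise ValueError("cv undefined for nonpositive mean")
    if arr.size == 1:
        return 0.0
    return float(np.std(arr, ddof=1) / mean)


def _binned_medians(
    cln3: np.ndarray, tg1: np.ndarray, bin_width: float, min_per_bin: int
) -> pd.DataFrame:
    """Median (Cln3, TG1) per Cln3-intensity bin, keeping bins with n > min."""
    edges = np.arange(0.0, cln3.max() + bin_width, bin_width)
    idx = np.digitize(cln3, edges) - 1
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        n = int(sel.sum())
        if n > min_per_bin:
            rows.append(
                {
                    "median_cln3": float(np.median(cln3[sel])),
                    "median_tg1": float(np.median(tg1[sel])),
                    "n": n,
                }
            )
    return pd.DataFrame(rows, columns=["median_cln3", "median_tg1", "n"])


def fit_loglog(
    records: Sequence[CellCycleRecord] | pd.DataFrame,
    marker: Literal["whi5", "mcm"] = "whi5",
    fit_mode: Literal["least_squares", "closest_to_minus_one"] = "closest_to_minus_one",
    *,
    bin_width: float = 100.0,
    min_per_bin: int = 10,
    cln3c_search: float = 200.0,
    cln3c_step: float = 1.0,
    cln3_c_fixed: float | None = None,
) -> LogLogFit:
    """Binned log-log fit of TG1 versus ⟨Cln3⟩ with asymptote search.

    For every candidate Cln3c on a grid over [min_Cln3 - 200, min_Cln3]
    (min_Cln3 = lowest ⟨Cln3⟩ that passed Start), the records are binned by
    Cln3 intensity, bins with more than ``min_per_bin`` points contribute
    their medians, and a straight line is fitted to
    log(median TG1 - T0) vs log(median Cln3 - Cln3c).  The Cln3c retained
    is the one with the highest R² (``least_squares``) or the one whose
    slope is closest to -1 (``closest_to_minus_one``).  ``cln3_c_fixed``
    bypasses the search (the whi5-null convention Cln3c = 0).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    t0 = T0_BY_MARKER[marker]
    usable = df[(df["tg1"] > t0)]
    if len(usable) < min_per_bin + 1:
        raise ValueError("too few records above the T0 asymptote")
    cln3 = usable["mean_cln3_g1"].to_numpy(dtype=float)
    tg1 = usable["tg1"].to_numpy(dtype=float)
    bins_all = _binned_medians(cln3, tg1, bin_width, min_per_bin)
    if len(bins_all) < 2:
        raise ValueError("fewer than 2 qualifying bins")
    min_cln3 = float(cln3.min())
    if cln3_c_fixed is not None:
        candidates = np.array([cln3_c_fixed])
    else:
        candidates = np.arange(
            max(min_cln3 - cln3c_search, 0.0), min_cln3 + 0.5 * cln3c_step, cln3c_step
        )
    best = None
    for cc in candidates:
        ok = (bins_all["median_cln3"] > cc) & (bins_all["median_tg1"] > t0)
        sub = bins_all[ok]
        if len(sub) < 2:
            continue
        x = np.log(sub["median_cln3"].to_numpy() - cc)
        y = np.log(sub["median_tg1"].to_numpy() - t0)
        res = linregress(x, y)
        r2 = float(res.rvalue**2)
        key = r2 if fit_mode == "least_squares" else -abs(res.slope + 1.0)
        if best is None or key > best[0]:
            best = (key, cc, res, sub, r2)
    if best is None:
        raise ValueError("no candidate Cln3c left >= 2 qualifying bins")
    _, cc, res, sub, r2 = best
    return LogLogFit(
        t0_fixed=t0,
        cln3_c=float(cc),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        bins=sub.reset_index(drop=True),
        fit_mode=fit_mode,
        n_records=int(len(usable)),
    )


def analyze_population(
    traces: Sequence[CellTrace],
    stiffness: float | None = None,
) -> tuple[pd.DataFrame, int]:
    """Run G1 extraction + quantification over many traces.

    Returns the table of per-cycle records and the number of rejected
    traces (no qualifying derivative extrema, or too short).
    """
    records = []
    rejected = 0
    for tr in traces:
        try:
            t_enter, t_exit, _ = extract_g1(tr.times, tr.whi5_nuclear_signal, stiffness)
            rec = quantify_cycle(tr, (t_enter, t_exit))
        except (ValueError, RuntimeError):
            rejected += 1
            continue
        records.append(rec.__dict__)
    cols = [
        "tg1", "mean_cln3_g1", "whi5_tot", "integral_a_est",
        "growth_rate", "lineage", "condition", "cell_id",
    ]
    return pd.DataFrame(records, columns=cols), rejected
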