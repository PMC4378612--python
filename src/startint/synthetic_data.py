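"""Synthetic single-cell time-lapse data with known ground truth.

Emulates the experimental input to the pipeline: per-cell fluorescence
traces on a 3-min imaging grid with a noisy Cln3 reporter channel and a
nuclear Whi5 channel showing G1 entry and exit.  Cln3 counts come from the
exact stochastic simulator; the nuclear Whi5 signal is driven by the
phosphorylation integrator, wrapped in logistic nuclear-entry/export ramps
so the derivative-based G1 extraction sees realistic extrema; multiplicative
lognormal noise models shot/detection noise.

Scenarios encode the experimental axes: Cln3 induction level (promoter
titration), Whi5 dosage (2XWHI5, nutrient modulation), phosphatase
overexpression, weakened Cln1/2 feedback, whi5-null cells that pass Start
with minimal G1, a Bck2 bypass cap on G1 length, and the mother/daughter
lineage mix.  Every generated cell carries its ground truth for
parameter-recovery tests, and every artifact is a pure function of
(specification, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cln3_stochastic import (
    Cln3KineticParams,
    ConcentrationTrace,
    ExtrinsicNoiseSpec,
    sample_extrinsic,
    ssa_simulate,
)
from .trace_analysis import FRAME_MIN, CellTrace
from .whi5_integrator import IntegratorParams, simulate_whi5p, tg1_from_integrator

__all__ = [
    "ScenarioSpec",
    "GroundTruth",
    "generate_cell",
    "generate_population",
    "generate_dephospho_traces",
    "default_induction_grid",
    "traces_to_frame",
    "frame_to_traces",
]

#: Mother/daughter asymmetry: daughters carry more Whi5, and only
#: daughters suffer the Ace2 early-G1 CLN3 suppression (the kinetic
#: parameter ``r``); mothers start G1 at full capacity.
DAUGHTER_WHI5_SCALE = 1.25

#: Logistic ramp time constants (min).  Entry is the slower Cdc14-driven
#: influx; export at Start is fast and begins EXPORT_DELAY after the
#: commitment decision (feedback build-up), with the nuclear level held at
#: its Start value through the export window.  Together these place the
#: steepest descent of the signal at TG1, so the derivative-based G1
#: extraction recovers the true G1 length without shape bias.
ENTRY_TAU = 1.5
EXPORT_TAU = 0.75
EXPORT_DELAY = 1.0

#: Fluorescence calibration of the Cln3 reporter channel (a.u. per
#: molecule of nuclear concentration): puts observed intensities on the
#: hundreds-of-a.u. scale that the binning and asymptote-search constants
#: of the log-log fit assume.
CLN3_GAIN = 4.0

#: Observation padding around the true G1 window (min).
PRE_ROLL = 9.0
POST_ROLL = 12.0

BACKGROUND_FRACTION = 0.05  # non-nuclear Whi5 background vs whi5_tot


@dataclass(frozen=True)
class ScenarioSpec:
    """One experimental condition for the generator.

    ``induction_scale`` multiplies the CLN3 transcription rate (promoter
    titration); ``whi5_tot_scale`` the Whi5 dosage (2XWHI5 / nutrients);
    ``k2_scale`` the phosphatase rate (CDC14 overexpression);
    ``whi5_c_scale`` (< 1) weakens the positive feedback (cln1/2 deletion);
    ``whi5_null`` makes cells pass Start at T0 with no integrator;
    ``bck2_cap`` truncates G1 at the Bck2 bypass time; ``lineage_mix`` is
    the fraction of daughter cells.  ``extrinsic_cv`` is the cell-to-cell
    parameter variability applied to kinetic and integrator parameters.
    """

    induction_scale: float = 1.0
    whi5_tot_scale: float = 1.0
    k2_scale: float = 1.0
    whi5_c_scale: float = 1.0
    whi5_null: bool = False
    bck2_cap: float | None = None
    lineage_mix: float = 0.5
    measurement_noise_cv: float = 0.10
    extrinsic_cv: float = 0.2
    n_cells: int = 120
    condition: str = "base"

    def __post_init__(self) -> None:
        for name in ("induction_scale", "whi5_tot_scale", "k2_scale", "whi5_c_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.lineage_mix <= 1:
            raise ValueError("lineage_mix must be in [0, 1]")
        if self.measurement_noise_cv < 0 or self.extrinsic_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        if self.bck2_cap is not None and self.bck2_cap <= 0:
            raise ValueError("bck2_cap must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """True per-cell quantities used to generate the trace."""

    tg1: float
    whi5_tot: float
    mean_cln3: float
    integral_a: float
    cln3_c: float
    t0: float
    tau: float | None
    lineage: str
    condition: str
    cell_id: str
    censored: bool = False


def _simulate_until_start(
    params: Cln3KineticParams,
    integrator: IntegratorParams,
    rng: np.random.Generator,
    t_max: float,
    chunk: float = 40.0,
):
    """Grow an SSA trace in chunks until the integrator fires (+ margin).

    The signal handed to the integrator (and later observed) is the
    volume-normalized concentration counts * exp(-alpha*t) in a.u. — the
    fluorescence-intensity convention of the measurements, under which the
    Cln3 process is stationary in G1.  Returns ``(cln3_trace, g1_result)``
    where the trace covers at least [0, tg1 + POST_ROLL] (or [0, t_max]
    when censored).
    """
    times = None
    state = None
    t_hi = 0.0
    while t_hi < t_max:
        t_next = min(t_hi + chunk, t_max)
        seg = ssa_simulate(
            params, t_next, rng, t_start=t_hi, initial=state
        )
        if times is None:
            times = seg.event_times
            prot = seg.protein_counts
        else:
            times = np.concatenate([times, seg.event_times[1:]])
            prot = np.concatenate([prot, seg.protein_counts[1:]])
        state = (int(seg.mrna_counts[-1]), int(seg.protein_counts[-1]))
        t_hi = t_next
        # counts are constant after the last event: close the trace with an
        # explicit endpoint at the simulated horizon
        t_eval = np.append(times, t_hi)
        p_eval = np.append(prot, prot[-1]).astype(float)
        conc = p_eval * np.exp(-params.alpha * t_eval)
        trace = ConcentrationTrace(times=t_eval, values=conc, units="au")
        g1 = tg1_from_integrator(trace, integrator)
        if not g1.censored and t_hi >= g1.tg1 + POST_ROLL:
            return trace, g1
    return trace, g1


def _logistic(t, center, tau):
    return 1.0 / (1.0 + np.exp(-(t - center) / tau))


def generate_cell(
    scenario: ScenarioSpec,
    params: Cln3KineticParams,
    integrator: IntegratorParams,
    seed,
    *,
    t_max: float = 180.0,
    cell_id: str = "cell",
) -> tuple[CellTrace, GroundTruth]:
    """Generate one cell's two-channel trace and its ground truth.

    Model time 0 is Whi5 nuclear entry (cytokinesis); the true G1 window is
    [0, TG1] with TG1 from the integrator driven by the cell's stochastic
    Cln3 realization.  The observed grid spans [-9, TG1 + 12] min at the
    3-min cadence.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    lineage = "daughter" if rng.random() < scenario.lineage_mix else "mother"
    cell_params = replace(params, a1=params.a1 * scenario.induction_scale)
    whi5_tot = integrator.whi5_tot * scenario.whi5_tot_scale
    if lineage == "daughter":
        # Ace2 suppresses CLN3 specifically in daughters; mothers start G1
        # at the full transcriptional capacity
        whi5_tot *= DAUGHTER_WHI5_SCALE
    else:
        cell_params = replace(cell_params, r=1.0)
    cell_integrator = replace(
        integrator,
        whi5_tot=whi5_tot,
        k2=integrator.k2 * scenario.k2_scale,
        whi5_c=min(integrator.whi5_c * scenario.whi5_c_scale, whi5_tot - 1e-9),
    )
    if scenario.extrinsic_cv > 0:
        noise = ExtrinsicNoiseSpec(cv=scenario.extrinsic_cv)
        # cell-to-cell Whi5 dosage scales the dischargeable reserve
        # (whi5_tot - whi5_c), i.e. the integration threshold A, rather
        # than collapsing whi5_tot onto the feedback set point
        gap = cell_integrator.whi5_tot - cell_integrator.whi5_c
        cell_params, (gap,) = sample_extrinsic(cell_params, [gap], noise, rng)
        cell_integrator = replace(
            cell_integrator, whi5_tot=cell_integrator.whi5_c + gap
        )

    cln3, g1 = _simulate_until_start(cell_params, cell_integrator, rng, t_max)
    tg1 = g1.tg1
    censored = g1.censored
    if scenario.whi5_null:
        tg1 = cell_integrator.t0 + 1.0  # minimal G1: no integrator to discharge
        censored = False
    if scenario.bck2_cap is not None and tg1 > scenario.bck2_cap:
        tg1 = scenario.bck2_cap  # Cln3-independent bypass trigger
        censored = False

    # observation grid around the true G1 window
    grid = np.arange(-PRE_ROLL, tg1 + POST_ROLL + 0.5 * FRAME_MIN, FRAME_MIN)
    # Cln3 channel: piecewise-constant concentration in calibrated a.u.
    # (pre-entry frames mirror t=0)
    idx = np.searchsorted(cln3.times, np.clip(grid, 0.0, cln3.times[-1]), side="right") - 1
    cln3_obs = CLN3_GAIN * cln3.values[np.clip(idx, 0, len(cln3.values) - 1)]

    # nuclear Whi5 channel: integrator concentration in entry/export ramps.
    # whi5-null cells still need a G1 readout (the MCM-style marker): a
    # plateau with the same entry/export ramps but no integrator decline.
    entry = _logistic(grid, 0.0, ENTRY_TAU)
    export = 1.0 - _logistic(grid, tg1 + EXPORT_DELAY, EXPORT_TAU)
    if scenario.whi5_null:
        plateau = 50.0
        base = BACKGROUND_FRACTION * plateau
        whi5_sig = base + (plateau - base) * entry * export
    else:
        t_w, _, nuc_vals = simulate_whi5p(cln3, cell_integrator)
        # hold the nuclear level at its Start value through the export
        # window so the export transition is the steepest descent
        t_eval = np.clip(np.minimum(grid, tg1), t_w[0], t_w[-1])
        nuc = np.interp(t_eval, t_w, nuc_vals)
        nuc[grid < cell_integrator.t0] = cell_integrator.whi5_tot
        base = BACKGROUND_FRACTION * cell_integrator.whi5_tot
        whi5_sig = base + (nuc - base) * entry * export
        whi5_sig = np.maximum(whi5_sig, 0.0)

    area = 1000.0 * np.exp(cell_params.alpha * (grid - grid[0]))
    if scenario.measurement_noise_cv > 0:
        sigma = np.sqrt(np.log1p(scenario.measurement_noise_cv**2))
        mu = -0.5 * sigma**2
        cln3_obs = cln3_obs * rng.lognormal(mu, sigma, size=grid.shape)
        whi5_sig = whi5_sig * rng.lognormal(mu, sigma, size=grid.shape)
        area = area * rng.lognormal(mu, sigma, size=grid.shape)

    trace = CellTrace(
        times=grid,
        cln3_signal=cln3_obs,
        whi5_nuclear_signal=whi5_sig,
        cell_area=area,
        lineage=lineage,
        condition=scenario.condition,
        cell_id=cell_id,
    )
    # true ⟨Cln3⟩ over the exact G1 window, from the event trace, reported
    # in the same calibrated a.u. as the observed channel
    mask_end = np.searchsorted(cln3.times, tg1)
    seg_t = np.concatenate([cln3.times[:mask_end], [tg1]])
    seg_v = cln3.values[: len(seg_t) - 1]
    mean_cln3 = (
        CLN3_GAIN * float(np.sum(seg_v * np.diff(seg_t)) / tg1) if tg1 > 0 else 0.0
    )
    truth = GroundTruth(
        tg1=float(tg1),
        whi5_tot=0.0 if scenario.whi5_null else float(cell_integrator.whi5_tot),
        mean_cln3=mean_cln3,
        integral_a=0.0
        if scenario.whi5_null
        else CLN3_GAIN
        * (cell_integrator.whi5_tot - cell_integrator.whi5_c)
        / cell_integrator.k1,
        cln3_c=0.0
        if scenario.whi5_null or cell_integrator.mode == "linear"
        else CLN3_GAIN * cell_integrator.k2 / cell_integrator.k1,
        t0=cell_integrator.t0,
        tau=None if cell_integrator.mode == "saturated" else 1.0 / cell_integrator.k2,
        lineage=lineage,
        condition=scenario.condition,
        cell_id=cell_id,
    )
    if censored:
        truth = replace(truth, censored=True)
    return trace, truth


def default_induction_grid(
    scales: Sequence[float] = (0.3, 0.5, 0.8, 1.1, 1.5),
    n_per_condition: int = 120,
    **overrides,
) -> list[ScenarioSpec]:
    """Promoter-titration scenario grid spanning a >4-fold Cln3 range.

    The default scales keep every condition inside the regime the 3-min
    imaging cadence can resolve: the shortest mean G1 stays a few frames
    above the T0 asymptote, while ⟨Cln3⟩ still spans 6-fold.
    """
    return [
        ScenarioSpec(
            induction_scale=s,
            n_cells=n_per_condition,
            condition=f"induction_{s:g}x",
            **overrides,
        )
        for s in scales
    ]


def generate_population(
    scenarios: Sequence[ScenarioSpec],
    seed,
    params: Cln3KineticParams | None = None,
    integrator: IntegratorParams | None = None,
    t_max: float = 180.0,
) -> tuple[list[CellTrace], pd.DataFrame]:
    """Generate a multi-condition population of cells.

    Returns the traces and the ground-truth table (censored cells are
    included in the truth table, flagged, but excluded from the traces as
    they never left G1 within the horizon).
    """
    if len(scenarios) == 0:
        raise ValueError("at least one scenario required")
    params = params or Cln3KineticParams()
    integrator = integrator or IntegratorParams()
    rng = np.random.default_rng(seed)
    traces: list[CellTrace] = []
    truth_rows = []
    for scen in scenarios:
        for i in range(scen.n_cells):
            cid = f"{scen.condition}_{i:04d}"
            trace, truth = generate_cell(
                scen, params, integrator, rng, t_max=t_max, cell_id=cid
            )
            truth_rows.append(truth.__dict__)
            if not truth.censored:
                traces.append(trace)
    return traces, pd.DataFrame(truth_rows)


def generate_dephospho_traces(
    tau: float,
    plateau: float,
    amplitude: float,
    noise_cv: float,
    n: int,
    seed,
    *,
    tau_sd: float = 0.0,
    t_max: float = 60.0,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Whi5 nuclear-entry recovery traces after Cdk1 inhibition.

    Each trace follows Whi5(t) = plateau - amplitude * exp(-t/tau_cell) on
    the 3-min grid with multiplicative Gaussian noise of CV ``noise_cv``
    relative to the plateau; ``tau_cell`` is drawn Normal(tau, tau_sd)
    truncated positive.  Returns the traces and the true per-cell taus.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + 0.5 * FRAME_MIN, FRAME_MIN)
    out = []
    taus = np.empty(n)
    for i in range(n):
        tau_i = tau
        if tau_sd > 0:
            tau_i = -1.0
            while tau_i <= 0:
                tau_i = rng.normal(tau, tau_sd)
        taus[i] = tau_i
        clean = plateau - amplitude * np.exp(-times / tau_i)
        noisy = clean + rng.normal(0.0, noise_cv * plateau, size=times.shape)
        out.append((times, noisy))
    return out, taus


def traces_to_frame(traces: Sequence[CellTrace]) -> pd.DataFrame:
    """Long-format trace table (the on-disk CSV layout)."""
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "time_min": tr.times,
                    "cln3_au": tr.cln3_signal,
                    "whi5_nuclear_au": tr.whi5_nuclear_signal,
                    "area_au": tr.cell_area
                    if tr.cell_area is not None
                    else np.nan,
                    "lineage": tr.lineage,
                    "condition": tr.condition,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[CellTrace]:
    """Rebuild CellTrace objects from the long-format table."""
    traces = []
    for cid, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("time_min")
        area = sub["area_au"].to_numpy(dtype=float)
        traces.append(
            CellTrace(
                times=sub["time_min"].to_numpy(dtype=float),
                cln3_signal=sub["cln3_au"].to_numpy(dtype=float),
                whi5_nuclear_signal=sub["whi5_nuclear_au"].to_numpy(dtype=float),
                cell_area=None if np.all(np.isnan(area)) else area,
                lineage=str(sub["lineage"].iloc[0]),
                condition=str(sub["condition"].iloc[0]),
                cell_id=str(cid),
            )
        )
    return traces
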