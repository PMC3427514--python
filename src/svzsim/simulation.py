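"""Full model runs: initial conditions, readouts and the solution
classifier.

A run starts from the imaging-experiment configuration — a Gaussian bolus
of labelled stem cells in the SVZ and a Gaussian chemoattractant profile
in the OB — and integrates the system for 300 days (or a configured
horizon).  The scalar readout ``ob_signal``, the OB-integrated density of
neuroblasts plus mature neurons, is the model's proxy for the in-vivo
bioluminescent photon flux.

The classifier sorts completed runs into three categories:

* ``physiological`` — fast equilibration of the SVZ pools to their
  algebraic steady states and a steady growth of the OB signal towards a
  plateau (controlled migration);
* ``non_neurogenic`` — stable dynamics but no appreciable neuronal
  maturation in the bulb, or an immediate constant-flux steady state;
* ``unphysical`` — failed integration, loss of positivity, blow-up, or
  growing oscillations of the OB signal.

All thresholds are explicit, documented fields of ClassifierConfig.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import (AuxiliaryFields, DomainSpec, Grid, build_aux_fields,
                       build_grid, gaussian_field)
from .model import (ConstraintReport, FieldState, ModelParameters,
                    check_constraints, steady_state_nB, steady_state_nC)
from .numerics import IntegrationResult, NumericsConfig, System

__all__ = [
    "TimeSeries", "SimulationResult", "ClassifierConfig",
    "ClassificationReport", "initial_state", "run_simulation", "ob_signal",
    "classify_solution",
]


@dataclass
class TimeSeries:
    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    @property
    def final(self) -> float:
        return float(self.values[-1])


@dataclass
class SimulationResult:
    """Saved trajectory of one run plus metadata and readouts.

    ``states`` has shape (n_saved, 5, n_active) in the field order
    (n_B, n_C, n_A, n_N, f_A).
    """

    times: np.ndarray
    states: np.ndarray
    readouts: dict[str, TimeSeries]
    solver_stats: dict
    failure_flag: bool
    params_used: ModelParameters
    grid: Grid
    config: NumericsConfig
    constraints: Optional[ConstraintReport] = None

    @property
    def n_saved(self) -> int:
        return len(self.times)

    def state_at(self, k: int) -> FieldState:
        s = self.states[k]
        return FieldState(*(s[i] for i in range(5)), t=float(self.times[k]))

    def initial_svz_total(self) -> float:
        svz = self.grid.masks["svz"]
        return float(self.states[0, 0, svz].sum() * self.grid.cell_area)


def initial_state(grid: Grid, spec: DomainSpec) -> FieldState:
    """Imaging-experiment initial conditions: no C/A cells or neurons;
    f_A a Gaussian in the OB (peak 1, width half the OB side); n_B a
    Gaussian bolus at the SVZ centre (peak 100, width 5/6 of half the SVZ
    side) truncated to the SVZ."""
    n = grid.n_active
    state = FieldState.zeros(n)
    ob_side = min(spec.ob_box.width, spec.ob_box.height)
    state.f_A = gaussian_field(grid, spec.ob_centre, 1.0, 0.5 * ob_side)
    svz_side = min(spec.svz_box.width, spec.svz_box.height)
    nB = gaussian_field(grid, spec.svz_box.centre, 100.0,
                        (5.0 / 6.0) * 0.5 * svz_side)
    state.n_B = np.where(grid.masks["svz"], nB, 0.0)
    return state


def _readouts(times: np.ndarray, states: np.ndarray, grid: Grid
              ) -> dict[str, TimeSeries]:
    area = grid.cell_area
    ob = grid.masks["ob"]
    svz = grid.masks["svz"]
    out: dict[str, TimeSeries] = {}
    sig = (states[:, 2, :][:, ob] + states[:, 3, :][:, ob]).sum(axis=1) * area
    out["ob_signal"] = TimeSeries(times, sig, "ob_signal")
    n_svz = max(int(svz.sum()), 1)
    out["svz_mean_nB"] = TimeSeries(
        times, states[:, 0, :][:, svz].sum(axis=1) / n_svz, "svz_mean_nB")
    out["svz_mean_nC"] = TimeSeries(
        times, states[:, 1, :][:, svz].sum(axis=1) / n_svz, "svz_mean_nC")
    for k, name in enumerate(FieldState.FIELDS):
        out[f"total_{name}"] = TimeSeries(
            times, states[:, k, :].sum(axis=1) * area, f"total_{name}")
    return out


def run_simulation(params: ModelParameters,
                   spec: DomainSpec | None = None,
                   config: NumericsConfig | None = None,
                   grid: Grid | None = None,
                   system: System | None = None) -> SimulationResult:
    """Integrate the full model from the imaging initial state.

    A pre-built ``grid``/``system`` may be supplied to amortise setup
    across a screening campaign; integration failure is reported through
    ``failure_flag``, never raised.
    """
    spec = spec or DomainSpec()
    config = config or NumericsConfig()
    if grid is None:
        grid = build_grid(spec)
    else:
        spec = grid.spec
    system = system or System(grid)
    aux = build_aux_fields(grid, params)
    y0 = system.pack_state(initial_state(grid, spec))
    res: IntegrationResult = _integrate_system(system, params, aux, y0, config)
    n = grid.n_active
    states = system.unpack_trajectory(res.states) if res.states.size \
        else np.zeros((1, 5, n))
    times = res.times if res.times.size else np.array([0.0])
    readouts = _readouts(times, states, grid)
    stats = {"nfev": res.nfev, "njev": res.njev, "n_saved": len(times),
             "message": res.message, "blew_up": res.blew_up}
    return SimulationResult(
        times=times, states=states, readouts=readouts, solver_stats=stats,
        failure_flag=not res.success, params_used=params, grid=grid,
        config=config, constraints=check_constraints(params))


def _integrate_system(system: System, params, aux, y0, config):
    from .numerics import integrate

    f = system.rhs(params, aux)
    return integrate(f, y0, (0.0, config.t_final), config,
                     jac_sparsity=system.jac_sparsity(),
                     jac=system.jac_fd(f))


def ob_signal(result: SimulationResult) -> TimeSeries:
    """OB-integrated (n_A + n_N) x cell area: the photon-flux proxy."""
    return result.readouts["ob_signal"]


@dataclass(frozen=True)
class ClassifierConfig:
    """Named thresholds of the qualitative solution classifier.

    The categories themselves are qualitative; every numeric cut below is
    a package decision, kept explicit and configurable.
    """

    negativity_rel: float = 1e-6        # positivity violation, relative to field max
    blowup_factor: float = 1e3          # x max initial value
    oscillation_after: float = 30.0     # ignore the early transient (days)
    max_sign_changes: int = 2           # of d(ob_signal)/dt, beyond = oscillatory
    slope_noise_rel: float = 1e-3       # |slope| below this x peak slope counts as 0
    dead_signal_rel: float = 1e-3       # x initial SVZ content -> no neurogenesis
    early_plateau_time: float = 30.0    # plateau before this -> constant-flux regime
    plateau_band: float = 0.01          # fraction of final value
    equil_band: float = 0.10            # band around the algebraic steady states
    equil_deadline: float = 100.0       # days (capped at the run horizon)
    monotone_dip: float = 0.01          # tolerated relative dips of ob_signal
    plateau_slope_ratio: float = 0.05   # final/peak slope, full-horizon runs
    short_horizon: float = 200.0        # below this the plateau may lie beyond T
    short_plateau_slope_ratio: float = 0.5  # growth must at least have decelerated
    min_frames: int = 50


@dataclass
class ClassificationReport:
    category: str
    criteria: dict[str, bool]
    metrics: dict[str, float]


def _sign_changes(slopes: np.ndarray, noise: float) -> int:
    s = np.sign(np.where(np.abs(slopes) > noise, slopes, 0.0))
    s = s[s != 0]
    return int(np.count_nonzero(np.diff(s) != 0)) if s.size else 0


def classify_solution(result: SimulationResult, params: ModelParameters,
                      cfg: ClassifierConfig | None = None
                      ) -> ClassificationReport:
    """Deterministic qualitative triage of one completed (or failed) run."""
    cfg = cfg or ClassifierConfig()
    crit: dict[str, bool] = {}
    met: dict[str, float] = {}

    completed = (not result.failure_flag
                 and result.n_saved >= cfg.min_frames
                 and float(result.times[-1]) >= result.config.t_final - 1e-9)
    crit["integration_completed"] = completed

    states = result.states
    init_max = max(float(np.max(states[0])), 1e-300)
    traj_max = float(np.max(states))
    met["max_field"] = traj_max
    positive = True
    for k in range(5):
        fmax = float(np.max(states[:, k, :]))
        if fmax > 0 and float(np.min(states[:, k, :])) < -cfg.negativity_rel * fmax:
            positive = False
    crit["positivity"] = positive
    crit["no_blowup"] = traj_max <= cfg.blowup_factor * init_max \
        and result.n_saved > 0 and not result.solver_stats.get("blew_up", False)

    sig = result.readouts["ob_signal"]
    t, s = sig.times, sig.values
    if t.size >= 3:
        slopes = np.diff(s) / np.diff(t)
        tm = 0.5 * (t[:-1] + t[1:])
        peak_slope = float(np.max(np.abs(slopes))) if slopes.size else 0.0
        noise = cfg.slope_noise_rel * peak_slope
        late = slopes[tm >= cfg.oscillation_after]
        osc = _sign_changes(late, noise)
    else:
        slopes = np.zeros(0)
        peak_slope = 0.0
        osc = 0
    met["oscillation_count"] = float(osc)
    crit["no_growing_oscillations"] = osc <= cfg.max_sign_changes

    if not (completed and positive and crit["no_blowup"]
            and crit["no_growing_oscillations"]):
        return ClassificationReport("unphysical", crit, met)

    # --- neurogenic output ---------------------------------------------
    final = sig.final
    met["final_ob_signal"] = final
    svz0 = result.initial_svz_total()
    crit["signal_detectable"] = final >= cfg.dead_signal_rel * svz0

    # plateau time: earliest time after which the signal stays within the
    # plateau band of its final value
    within = np.abs(s - final) <= cfg.plateau_band * max(abs(final), 1e-300)
    k = len(within)
    while k > 0 and within[k - 1]:
        k -= 1
    plateau_time = float(t[k]) if k < len(t) else float(t[-1])
    met["plateau_time"] = plateau_time
    crit["not_constant_flux"] = plateau_time >= cfg.early_plateau_time

    if not (crit["signal_detectable"] and crit["not_constant_flux"]):
        return ClassificationReport("non_neurogenic", crit, met)

    # --- physiological checks ------------------------------------------
    # "steady, controlled migration" means taxis-driven transport with a
    # sustainable SVZ cascade: the in-vivo admissibility constraints
    # (positive algebraic steady states, eta_i > delta_i).  A
    # diffusion-dominated run can still grow and plateau but is not a
    # controlled-migration solution.
    constraints = check_constraints(params)
    crit["controlled_migration"] = bool(constraints.passed)

    deadline = min(cfg.equil_deadline, float(result.times[-1]))
    equil = True
    for name, star_fn in (("svz_mean_nB", steady_state_nB),
                          ("svz_mean_nC", steady_state_nC)):
        try:
            star = star_fn(params)
        except ValueError:
            star = -1.0
        series = result.readouts[name]
        met[f"{name}_star"] = star
        if star <= 0:
            equil = False
            continue
        inband = np.abs(series.values / star - 1.0) <= cfg.equil_band
        # first index from which the series stays in-band to the end
        stay = len(inband)
        while stay > 0 and inband[stay - 1]:
            stay -= 1
        t_eq = float(series.times[stay]) if stay < len(inband) else np.inf
        met[f"{name}_equil_time"] = t_eq
        if t_eq > deadline:
            equil = False
    crit["svz_equilibration"] = equil

    running_max = np.maximum.accumulate(s)
    grows = bool(np.all(s >= running_max - cfg.monotone_dip
                        * np.maximum(running_max, 1e-300)))
    crit["monotone_growth"] = grows

    horizon = float(result.times[-1])
    ratio = (cfg.plateau_slope_ratio if horizon >= cfg.short_horizon
             else cfg.short_plateau_slope_ratio)
    final_slope = float(slopes[-1]) if slopes.size else 0.0
    met["final_slope_ratio"] = final_slope / peak_slope if peak_slope else 0.0
    crit["plateau_reached"] = peak_slope == 0.0 or \
        final_slope <= ratio * peak_slope

    if equil and grows and crit["plateau_reached"] \
            and crit["controlled_migration"]:
        return ClassificationReport("physiological", crit, met)
    return ClassificationReport("non_neurogenic", crit, met)
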