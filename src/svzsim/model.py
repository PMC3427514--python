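"""Kinetics of the five-species neurogenesis model.

Species: n_B (stem cells), n_C (transit-amplifying cells), n_A (migratory
neuroblasts), n_N (mature neurons) and f_A (the diffusible chemoattractant).
B and C cells are fixed in space and exist only in the SVZ; A cells
proliferate logistically (faster inside the SVZ), chemotax up the f_A
gradient and, inside the OB-centre square, either die at the boosted rate
gamma_A + eps or specify into neurons at rate zeta = mu*eps.  Mature
neurons diffuse and drift against the static dispersal field g, emulating
radial outward migration in the bulb.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .geometry import AuxiliaryFields, Grid

__all__ = [
    "PARAM_NAMES", "ModelParameters", "FieldState", "ConstraintReport",
    "reference_parameters", "reaction_rhs", "steady_state_nB",
    "steady_state_nC", "check_constraints",
]

#: canonical coordinate order for vectorised parameter-space work
PARAM_NAMES = (
    "beta_B", "beta_C", "beta_Ai", "beta_Ao",
    "alpha_C", "alpha_A",
    "gamma_B", "gamma_C", "gamma_A", "gamma_N",
    "delta_A", "delta_N", "delta_fA",
    "eta_A", "eta_N",
    "kappa_A", "kappa_B", "kappa_C", "kappa_D",
    "lam",
    "a_1", "a_2", "a_4", "a_5",
    "b", "d", "mu",
)


@dataclass(frozen=True)
class ModelParameters:
    """The 27 non-dimensional rate/transport/geometry constants.

    Units (with time in days, lengths in model units of 1.4 mm):
    beta_* logistic growth (1/day); alpha_C the B->C and alpha_A the C->A
    specification rate (1/day); gamma_* apoptosis (1/day); delta_*
    diffusion (length^2/day); eta_* taxis coefficients; kappa_A/B/C
    attractant production, kappa_D uptake, lam decay (1/day); a_1/a_2 the
    OB source Gaussian amplitude/width, a_4/a_5 the dispersal-field
    Gaussian; b the OB-centre square side; d the apoptosis-boost
    magnitude eps inside that square; mu the specification/apoptosis
    ratio (zeta = mu*eps).
    """

    beta_B: float
    beta_C: float
    beta_Ai: float
    beta_Ao: float
    alpha_C: float
    alpha_A: float
    gamma_B: float
    gamma_C: float
    gamma_A: float
    gamma_N: float
    delta_A: float
    delta_N: float
    delta_fA: float
    eta_A: float
    eta_N: float
    kappa_A: float
    kappa_B: float
    kappa_C: float
    kappa_D: float
    lam: float
    a_1: float
    a_2: float
    a_4: float
    a_5: float
    b: float
    d: float
    mu: float

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
        if self.a_2 <= 0 or self.a_5 <= 0:
            raise ValueError("Gaussian widths a_2, a_5 must be positive")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        others = min(self.gamma_B, self.gamma_C, self.gamma_A)
        if others > 0 and self.gamma_N > 0.5 * others:
            warnings.warn(
                "gamma_N is not small relative to the other apoptosis rates; "
                "mature neurons are expected to be long-lived",
                stacklevel=2)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES])

    @classmethod
    def from_array(cls, theta) -> "ModelParameters":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} coordinates")
        return cls(**dict(zip(PARAM_NAMES, theta.tolist())))

    def replace(self, **kw) -> "ModelParameters":
        d = {k: getattr(self, k) for k in PARAM_NAMES}
        d.update(kw)
        return ModelParameters(**d)

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}


def reference_parameters() -> ModelParameters:
    """The physiological exemplar parameter set shipped with the package."""
    import importlib.resources
    import tomllib

    text = (importlib.resources.files("svzsim") / "data"
            / "reference_parameters.toml").read_text()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ModelParameters(**tomllib.loads(text)["parameters"])


@dataclass
class FieldState:
    """The five fields on a grid at one instant (non-dimensional)."""

    n_B: np.ndarray
    n_C: np.ndarray
    n_A: np.ndarray
    n_N: np.ndarray
    f_A: np.ndarray
    t: float = 0.0

    FIELDS = ("n_B", "n_C", "n_A", "n_N", "f_A")

    def pack(self) -> np.ndarray:
        return np.concatenate([getattr(self, f) for f in self.FIELDS])

    @classmethod
    def unpack(cls, y: np.ndarray, n: int, t: float = 0.0) -> "FieldState":
        parts = [y[k * n:(k + 1) * n] for k in range(5)]
        return cls(*parts, t=t)

    @classmethod
    def zeros(cls, n: int, t: float = 0.0) -> "FieldState":
        return cls(*(np.zeros(n) for _ in range(5)), t=t)


def reaction_rhs(state: FieldState, aux: AuxiliaryFields,
                 params: ModelParameters, grid: Grid) -> FieldState:
    """Pointwise kinetics (no transport).

    B and C cells evolve only inside the SVZ; the type-A logistic rate is
    beta_Ai inside the SVZ and beta_Ao elsewhere; inside the OB-centre
    square type-A cells are lost at gamma_A + eps + zeta, of which
    zeta*n_A reappears as mature neurons.
    """
    n = grid.n_active
    for f in FieldState.FIELDS:
        if getattr(state, f).shape != (n,):
            raise ValueError(f"field {f} does not match the grid "
                             f"({getattr(state, f).shape} vs ({n},))")
    p = params
    svz = grid.masks["svz"]
    nB, nC, nA, nN, fA = state.n_B, state.n_C, state.n_A, state.n_N, state.f_A

    dnB = np.where(svz,
                   p.beta_B * nB * (1.0 - nB) - (p.alpha_C + p.gamma_B) * nB,
                   0.0)
    dnC = np.where(svz,
                   p.beta_C * nC * (1.0 - nC) + p.alpha_C * nB
                   - (p.alpha_A + p.gamma_C) * nC,
                   0.0)
    beta_A = np.where(svz, p.beta_Ai, p.beta_Ao)
    dnA = (beta_A * nA * (1.0 - nA) + p.alpha_A * nC
           - (p.gamma_A + aux.eps + aux.zeta) * nA)
    dnN = aux.zeta * nA - p.gamma_N * nN
    dfA = (p.kappa_A * nA + p.kappa_B * nB + p.kappa_C * nC
           - p.kappa_D * fA * nA - p.lam * fA + aux.q)
    return FieldState(dnB, dnC, dnA, dnN, dfA, t=state.t)


def steady_state_nB(params: ModelParameters) -> float:
    """Non-trivial spatially-uniform steady state of the stem-cell pool,
    n_B* = 1 - (alpha_C + gamma_B)/beta_B (the n_B = 0 root is ignored)."""
    if params.beta_B <= 0:
        raise ValueError("steady state undefined for beta_B = 0")
    return 1.0 - (params.alpha_C + params.gamma_B) / params.beta_B


def steady_state_nC(params: ModelParameters) -> float:
    """Largest root of beta_C n^2 - (beta_C - alpha_A - gamma_C) n
    - alpha_C n_B* = 0, the steady transit-amplifying density fed by the
    stem-cell influx alpha_C n_B*.  Non-positive when the pool cannot be
    sustained (reported, not raised)."""
    if params.beta_C <= 0:
        raise ValueError("steady state undefined for beta_C = 0")
    nB = steady_state_nB(params)
    bq = params.beta_C - params.alpha_A - params.gamma_C
    c = params.alpha_C * nB
    disc = bq * bq + 4.0 * params.beta_C * c
    if disc < 0:
        # complex roots: report the (non-positive) real part
        return bq / (2.0 * params.beta_C)
    return (bq + math.sqrt(disc)) / (2.0 * params.beta_C)


@dataclass
class ConstraintReport:
    """Admissibility screen applied before/alongside a simulation:
    positive algebraic steady states and taxis dominating diffusion."""

    nB_star: float
    nC_star: float
    steady_states_positive: bool
    taxis_dominates_diffusion: bool
    passed: bool
    messages: list[str]


def check_constraints(params: ModelParameters) -> ConstraintReport:
    msgs: list[str] = []
    try:
        nB = steady_state_nB(params)
        nC = steady_state_nC(params)
    except ValueError as exc:
        return ConstraintReport(float("nan"), float("nan"), False, False,
                                False, [str(exc)])
    ss_pos = nB > 0 and nC > 0
    if not ss_pos:
        msgs.append(f"non-positive steady state: nB*={nB:.4g}, nC*={nC:.4g}")
    taxis = params.eta_A > params.delta_A and params.eta_N > params.delta_N
    if not taxis:
        msgs.append("taxis does not dominate diffusion "
                    f"(eta_A={params.eta_A:.4g} vs delta_A={params.delta_A:.4g}, "
                    f"eta_N={params.eta_N:.4g} vs delta_N={params.delta_N:.4g})")
    return ConstraintReport(nB, nC, ss_pos, taxis, ss_pos and taxis, msgs)
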