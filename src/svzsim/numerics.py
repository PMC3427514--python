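"""Method-of-lines machinery for the taxis-diffusion-reaction system.

Space is discretized on the cell-centred grid: diffusion by the standard
second-order five-point stencil with ghost-cell reflection at the domain
boundary (zero normal flux), taxis in conservative face-flux form with
first/second-order upwind reconstruction limited by the van Leer function
to keep solutions positive.  The resulting stiff ODE system is advanced
by an adaptive implicit integrator with a per-step local error tolerance
(default 1e-6) and a sparse finite-difference Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .geometry import AuxiliaryFields, Grid
from .model import FieldState, ModelParameters, reaction_rhs

__all__ = [
    "NumericsConfig", "van_leer", "laplacian_zero_flux", "taxis_divergence",
    "assemble_rhs", "integrate", "IntegrationResult", "System",
]


@dataclass(frozen=True)
class NumericsConfig:
    """Integration contract: local error per step below ``tolerance``,
    output at ``save_times`` (default: every save_every days up to t_final),
    at most ``max_nfev`` right-hand-side evaluations before a run is
    declared failed."""

    tolerance: float = 1e-6
    t_final: float = 300.0
    save_every: float = 1.0
    save_times: np.ndarray | None = None
    max_nfev: int = 2_000_000
    limiter: str = "van-leer"
    blowup_factor: float = 1e3   # terminate when any field tops this x initial max
    method: str = "BDF"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.save_times is not None:
            st = np.asarray(self.save_times, dtype=float)
            if st.ndim != 1 or st.size < 2 or np.any(np.diff(st) <= 0):
                raise ValueError("save_times must be strictly increasing")
            object.__setattr__(self, "save_times", st)

    def resolved_save_times(self) -> np.ndarray:
        if self.save_times is not None:
            return self.save_times
        n = int(round(self.t_final / self.save_every))
        return np.linspace(0.0, self.t_final, n + 1)


def van_leer(r: np.ndarray) -> np.ndarray:
    """Flux limiter phi(r) = (r + |r|)/(1 + |r|): 0 for r <= 0 (local
    extremum -> first-order upwind), 1 at r = 1, bounded by 2."""
    r = np.asarray(r, dtype=float)
    return (r + np.abs(r)) / (1.0 + np.abs(r))


def _prepared_faces(grid: Grid):
    """Cached per-grid face arrays with out-of-domain upwind neighbours
    replaced by a safe index plus a validity factor."""
    cached = getattr(grid, "_prepared_faces", None)
    if cached is not None:
        return cached
    prepared = []
    for L, R, LL, RR in (grid.faces_x, grid.faces_y):
        hasLL = (LL >= 0).astype(float)
        hasRR = (RR >= 0).astype(float)
        prepared.append((L, R, np.where(LL >= 0, LL, L),
                         np.where(RR >= 0, RR, R), hasLL, hasRR))
    grid._prepared_faces = prepared
    return prepared


def laplacian_zero_flux(u: np.ndarray, grid: Grid) -> np.ndarray:
    """Five-point Laplacian with reflecting (zero-flux) closure: a missing
    neighbour contributes nothing, so row sums vanish and the discrete
    integral of the output is identically zero."""
    n = grid.n_active
    h2 = grid.h * grid.h
    out = np.zeros(n)
    for L, R, *_ in _prepared_faces(grid):
        d = u[R] - u[L]
        out += np.bincount(L, d, minlength=n)
        out -= np.bincount(R, d, minlength=n)
    out /= h2
    return out


def _face_flux(u, p, coeff, sign, faces, h):
    """Limited upwind flux through one set of faces.  Returns the flux
    J (positive = from L to R) per face."""
    L, R, LLs, RRs, hasLL, hasRR = faces
    v = (sign * coeff / h) * (p[R] - p[L])     # transport velocity at face
    du = u[R] - u[L]
    pos = v >= 0.0
    # slope one cell upwind of the face (0 at the boundary closure)
    num = np.where(pos, (u[L] - u[LLs]) * hasLL, (u[RRs] - u[R]) * hasRR)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(du != 0.0, num / du, 0.0)
    phi = (r + np.abs(r)) / (1.0 + np.abs(r))
    uface = np.where(pos, u[L] + 0.5 * phi * du, u[R] - 0.5 * phi * du)
    return v * uface


def taxis_divergence(density: np.ndarray, potential: np.ndarray,
                     coefficient: float, sign: str, grid: Grid) -> np.ndarray:
    """Discrete -div(coefficient * density * v) with v = +grad(potential)
    for ``sign='attract'`` and v = -grad(potential) for ``'repel'``.
    Face fluxes are upwinded with the van Leer limiter; boundary faces
    carry no flux, so the output sums to zero exactly."""
    if not np.all(np.isfinite(potential)):
        raise FloatingPointError("taxis potential contains non-finite values")
    s = {"attract": 1.0, "repel": -1.0}[sign]
    n = grid.n_active
    out = np.zeros(n)
    for faces in _prepared_faces(grid):
        J = _face_flux(density, potential, coefficient, s, faces, grid.h)
        out -= np.bincount(faces[0], J, minlength=n)
        out += np.bincount(faces[1], J, minlength=n)
    out /= grid.h
    return out


def assemble_rhs(state: FieldState, params: ModelParameters,
                 aux: AuxiliaryFields, grid: Grid) -> FieldState:
    """Full semi-discrete right-hand side: kinetics plus diffusion of
    n_A, n_N, f_A, chemotaxis of n_A up grad f_A, and drift of n_N down
    grad g.  Stem and transit-amplifying cells receive no transport."""
    rate = reaction_rhs(state, aux, params, grid)
    rate.n_A = (rate.n_A + params.delta_A * laplacian_zero_flux(state.n_A, grid)
                + taxis_divergence(state.n_A, state.f_A, params.eta_A,
                                   "attract", grid))
    rate.n_N = (rate.n_N + params.delta_N * laplacian_zero_flux(state.n_N, grid)
                + taxis_divergence(state.n_N, aux.g, params.eta_N,
                                   "repel", grid))
    rate.f_A = rate.f_A + params.delta_fA * laplacian_zero_flux(state.f_A, grid)
    return rate


class System:
    """Packed-vector view of the semi-discrete system on one grid.

    Stem (n_B) and transit-amplifying (n_C) cells exist only inside the
    SVZ, so their degrees of freedom are stored on SVZ cells alone; the
    packed vector is [n_B|svz, n_C|svz, n_A, n_N, f_A].  The Jacobian
    sparsity pattern and its column coloring are cached and reused
    across parameter sets on the same grid.
    """

    def __init__(self, grid: Grid):
        self.grid = grid
        self._sparsity = None
        self._colors = None
        self.svz_idx = np.nonzero(grid.masks["svz"])[0]
        self.n = grid.n_active
        self.m = self.svz_idx.size
        self.ndof = 2 * self.m + 3 * self.n

    # -- packing --------------------------------------------------------
    def pack_state(self, state: FieldState) -> np.ndarray:
        return np.concatenate([state.n_B[self.svz_idx],
                               state.n_C[self.svz_idx],
                               state.n_A, state.n_N, state.f_A])

    def unpack_state(self, y: np.ndarray, t: float = 0.0) -> FieldState:
        n, m = self.n, self.m
        nB = np.zeros(n)
        nC = np.zeros(n)
        nB[self.svz_idx] = y[:m]
        nC[self.svz_idx] = y[m:2 * m]
        o = 2 * m
        return FieldState(nB, nC, y[o:o + n], y[o + n:o + 2 * n],
                          y[o + 2 * n:o + 3 * n], t=t)

    def unpack_trajectory(self, states: np.ndarray) -> np.ndarray:
        """(T, ndof) packed states -> (T, 5, n_active) full fields."""
        T = states.shape[0]
        n, m = self.n, self.m
        out = np.zeros((T, 5, n))
        out[:, 0, self.svz_idx] = states[:, :m]
        out[:, 1, self.svz_idx] = states[:, m:2 * m]
        o = 2 * m
        out[:, 2, :] = states[:, o:o + n]
        out[:, 3, :] = states[:, o + n:o + 2 * n]
        out[:, 4, :] = states[:, o + 2 * n:]
        return out

    def rhs(self, params: ModelParameters, aux: AuxiliaryFields,
            compiled: bool | None = None):
        """Packed rhs callable f(t, y).

        Uses the compiled kernel when numba is available (``compiled``
        forces either path); the numpy path via :func:`assemble_rhs` is
        the reference implementation.
        """
        from . import _kernels

        if compiled is None:
            compiled = _kernels.HAVE_NUMBA
        if not compiled:
            def f(t: float, y: np.ndarray) -> np.ndarray:
                state = self.unpack_state(y, t)
                rate = assemble_rhs(state, params, aux, self.grid)
                return self.pack_state(rate)

            return f

        grid = self.grid
        svz = grid.masks["svz"]
        beta_A = np.where(svz, params.beta_Ai, params.beta_Ao)
        gamma_A_eff = params.gamma_A + aux.eps + aux.zeta
        (fxL, fxR, fxLLs, fxRRs, fxHL, fxHR), \
            (fyL, fyR, fyLLs, fyRRs, fyHL, fyHR) = _prepared_faces(grid)
        pv = params.as_array()
        zeta, q, g = aux.zeta, aux.q, aux.g
        h = grid.h
        svz_idx = self.svz_idx

        def f(t: float, y: np.ndarray) -> np.ndarray:
            return _kernels.rhs_kernel(
                y, svz_idx, beta_A, gamma_A_eff, zeta, q, g,
                fxL, fxR, fxLLs, fxRRs, fxHL, fxHR,
                fyL, fyR, fyLLs, fyRRs, fyHL, fyHR, h, pv)

        return f

    def jac_sparsity(self) -> sp.csc_matrix:
        """Block pattern of the Jacobian: reactions couple the five fields
        pointwise; transport couples each transported field to its 2-ring
        axis neighbours (the limiter reaches two cells upwind) and n_A to
        the 1-ring of f_A through the face velocities."""
        if self._sparsity is not None:
            return self._sparsity
        g, n, m = self.grid, self.n, self.m
        eye = np.arange(n)
        pairs = [(eye, eye)]
        for d in range(4):
            nb = g.nbr[d]
            ok = nb >= 0
            pairs.append((eye[ok], nb[ok]))
            # two steps along the same axis
            nn = np.where(nb >= 0, g.nbr[d, np.where(nb >= 0, nb, 0)], -1)
            ok2 = nn >= 0
            pairs.append((eye[ok2], nn[ok2]))
        rows = np.concatenate([r for r, _ in pairs])
        cols = np.concatenate([c for _, c in pairs])
        near = sp.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
        diag_n = sp.identity(n, format="coo")
        diag_m = sp.identity(m, format="coo")
        # injection of SVZ-resident fields into full-grid equations
        P = sp.coo_matrix((np.ones(m), (self.svz_idx, np.arange(m))),
                          shape=(n, m))

        B, C, A, N, F = 0, 1, 2, 3, 4
        blocks = [[None] * 5 for _ in range(5)]
        blocks[B][B] = diag_m
        blocks[C][B] = diag_m
        blocks[C][C] = diag_m
        blocks[A][A] = near
        blocks[A][C] = P
        blocks[A][F] = near
        blocks[N][N] = near
        blocks[N][A] = diag_n
        blocks[F][F] = near
        blocks[F][A] = diag_n
        blocks[F][B] = P
        blocks[F][C] = P
        self._sparsity = sp.bmat(blocks, format="csc")
        self._sparsity.data[:] = 1.0
        self._sparsity.sum_duplicates()
        return self._sparsity

    # -- grouped finite-difference Jacobian -----------------------------
    def _coloring(self):
        """Greedy column coloring: columns sharing a row get distinct
        colors, so all columns of one color can be perturbed together."""
        if getattr(self, "_colors", None) is not None:
            return self._colors
        S = self.jac_sparsity().tocsc()
        conflict = (S.T @ S).tocsr()
        ndof = S.shape[1]
        color = -np.ones(ndof, dtype=np.int64)
        for c in range(ndof):
            nbrs = conflict.indices[conflict.indptr[c]:conflict.indptr[c + 1]]
            used = set(color[nbrs[nbrs < c]].tolist())
            k = 0
            while k in used:
                k += 1
            color[c] = k
        self._colors = color
        return color

    def jac_fd(self, f):
        """Sparse forward-difference Jacobian of the packed rhs ``f``,
        evaluating one rhs call per color group (far fewer than one per
        column)."""
        S = self.jac_sparsity().tocsc()
        color = self._coloring()
        ngroups = int(color.max()) + 1
        ndof = S.shape[1]
        nnz_col = np.repeat(np.arange(ndof), np.diff(S.indptr))
        groups = []
        for g in range(ngroups):
            cols = np.nonzero(color == g)[0]
            pos = np.nonzero(color[nnz_col] == g)[0]
            groups.append((cols, pos, S.indices[pos], nnz_col[pos]))
        sqeps = np.sqrt(np.finfo(float).eps)

        def jac(t, y):
            f0 = f(t, y)
            data = np.zeros(S.nnz)
            h = sqeps * np.maximum(np.abs(y), 1e-5)
            inv_h = 1.0 / h
            for cols, pos, rows, col_of in groups:
                dy = np.zeros(ndof)
                dy[cols] = h[cols]
                df = f(t, y + dy) - f0
                data[pos] = df[rows] * inv_h[col_of]
            return sp.csc_matrix((data, S.indices.copy(), S.indptr.copy()),
                                 shape=S.shape)

        return jac


@dataclass
class IntegrationResult:
    """Raw integrator output on the packed state vector."""

    times: np.ndarray
    states: np.ndarray            # (n_saved, n_dof)
    success: bool
    message: str
    nfev: int = 0
    njev: int = 0
    n_steps: int = 0
    blew_up: bool = False


class _BudgetExceeded(RuntimeError):
    pass


def integrate(rhs, y0: np.ndarray, t_span, config: NumericsConfig,
              jac_sparsity=None, jac=None) -> IntegrationResult:
    """Adaptive stiff integration of y' = rhs(t, y) with local error held
    below ``config.tolerance`` per step.

    On blow-up (any component exceeding blowup_factor x the initial
    maximum, floored at 1) the run terminates early; on a solver failure
    or an exhausted evaluation budget the partial trajectory is returned
    with ``success=False``.  The contract is error control and stiff
    stability, not a particular implicit formula.
    """
    y0 = np.asarray(y0, dtype=float)
    t0, t1 = float(t_span[0]), float(t_span[1])
    save = config.resolved_save_times()
    save = save[(save >= t0) & (save <= t1)]
    if save.size == 0 or save[0] != t0:
        save = np.concatenate([[t0], save])
    cap = config.blowup_factor * max(1.0, float(np.max(np.abs(y0))))
    nfev_budget = config.max_nfev
    counter = {"n": 0}

    def guarded(t, y):
        counter["n"] += 1
        if counter["n"] > nfev_budget:
            raise _BudgetExceeded
        return rhs(t, y)

    def blowup(t, y):
        return cap - np.max(np.abs(y))

    blowup.terminal = True
    blowup.direction = -1

    kwargs = dict(method=config.method, t_eval=save,
                  rtol=config.tolerance, atol=config.tolerance * 1e-3,
                  events=blowup, dense_output=False)
    if config.method in ("BDF", "Radau"):
        if jac is not None:
            kwargs["jac"] = jac
        elif jac_sparsity is not None:
            kwargs["jac_sparsity"] = jac_sparsity
    try:
        sol = solve_ivp(guarded, (t0, t1), y0, **kwargs)
    except _BudgetExceeded:
        return IntegrationResult(np.array([t0]), y0[None, :], False,
                                 f"evaluation budget {nfev_budget} exhausted",
                                 nfev=counter["n"], blew_up=False)
    blew = sol.status == 1
    success = sol.status == 0
    return IntegrationResult(
        times=sol.t, states=sol.y.T,
        success=success,
        message="blow-up detected" if blew else sol.message,
        nfev=sol.nfev, njev=getattr(sol, "njev", 0) or 0,
        n_steps=len(sol.t), blew_up=blew)
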