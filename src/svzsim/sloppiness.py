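"""Sloppiness analysis: the deviation metric zeta^2, scattered-data
interpolation of its surface, finite-difference Hessians and the
eigen-spectrum diagnostics.

zeta^2(theta) is the squared L2 distance, integrated over space and
time and summed over the five species, between the trajectory at theta
and the trajectory at a reference theta*, divided by A = 2 T_c N_s.
Because PDE solves are expensive, the surface is reconstructed from a
Monte-Carlo cloud of (theta, zeta^2) samples by scattered-data
interpolation; the Hessian of the surface at theta* then gives the
principal axes of the local deviation ellipsoids.  A spectrum whose
eigenvalue magnitudes span many decades without a sharp gap is the
signature of a sloppy model: only a few stiff parameter combinations
are constrained by the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.interpolate import RBFInterpolator

from .model import PARAM_NAMES, ModelParameters
from .simulation import SimulationResult

__all__ = [
    "MetricSample", "MetricSurface", "SloppinessReport", "zeta_squared",
    "fit_surface", "hessian", "hessian_at", "eigen_spectrum",
]

N_SPECIES = 5


def zeta_squared(result: SimulationResult,
                 reference: SimulationResult) -> float:
    """Deviation metric between two trajectories on a common grid:

        zeta^2 = (1/A) * sum_i  intintint (u_i - u_i*)^2 dx dy dt,
        A = 2 * T_c * N_s,  N_s = 5,

    with the spatial integral evaluated by trapezoidal quadrature applied
    successively in x then y (honouring the box-union geometry) and the
    time integral by the trapezoidal rule over the saved frames.
    """
    if result.grid.n_active != reference.grid.n_active \
            or result.grid.h != reference.grid.h:
        raise ValueError("results live on different grids")
    if result.times.shape != reference.times.shape \
            or not np.allclose(result.times, reference.times):
        raise ValueError("results saved at different times")
    if result.failure_flag or reference.failure_flag:
        raise ValueError("zeta^2 is undefined for failed runs")
    w = result.grid.trapezoid_weights()
    diff2 = (result.states - reference.states) ** 2     # (T, 5, N)
    space = diff2 @ w                                   # (T, 5)
    t = result.times
    T_c = float(t[-1] - t[0])
    per_species = np.trapezoid(space, t, axis=0)
    A = 2.0 * T_c * N_SPECIES
    return float(per_species.sum() / A)


@dataclass
class MetricSample:
    """One evaluated point of the zeta^2 landscape."""

    theta: ModelParameters
    zeta2: float
    provenance: str = "simulated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.zeta2 < 0:
            raise ValueError("zeta2 must be non-negative")


def _coords(thetas: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return thetas / scale


class MetricSurface:
    """Scattered-data interpolant of zeta^2 over parameter space.

    Coordinates are scaled per-dimension by the spread of the training
    cloud so that the interpolant is well conditioned despite parameter
    magnitudes differing by orders.  Degenerate (constant) dimensions are
    projected out.  Backends:

    * ``"obtuse-angle"`` (default): angular-distance-weighted modified
      Shepard interpolation — inverse-distance weights attenuated for
      sample points shadowed behind others (a node keeps full weight
      only when seen under obtuse angles from the rest), blending local
      nodal models fitted around each node (quadratic where the cloud
      supports it, else linear, else constant), so the interpolant
      carries genuine curvature for Hessian estimation;
    * ``"idw"``: plain inverse-distance weighting;
    * ``"rbf"``: thin-plate-spline radial basis interpolation
      (cross-check backend).

    All backends reproduce the training values exactly at the nodes.
    """

    def __init__(self, thetas: np.ndarray, values: np.ndarray,
                 method: str = "obtuse-angle", idw_power: float = 4.0):
        thetas = np.asarray(thetas, dtype=float)
        values = np.asarray(values, dtype=float)
        if thetas.ndim != 2 or thetas.shape[0] != values.shape[0]:
            raise ValueError("thetas and values are inconsistent")
        self.method = method
        self.thetas = thetas
        self.values = values
        spread = thetas.max(axis=0) - thetas.min(axis=0)
        self.active = spread > 0
        base = np.where(self.active, spread, 1.0)
        centre = thetas.mean(axis=0)
        self.scale = np.where(base > 0, base, np.maximum(np.abs(centre), 1.0))
        self.X = (thetas / self.scale)[:, self.active]
        self.idw_power = idw_power
        self._rbf = None
        self._planes = None
        if method == "rbf":
            if len(values) >= 2:
                self._rbf = RBFInterpolator(self.X, values,
                                            kernel="thin_plate_spline")
        elif method in ("obtuse-angle", "idw"):
            if method == "obtuse-angle" and len(values) >= 2:
                self._planes = self._fit_local_models()
        else:
            raise ValueError(f"unknown interpolation method {method!r}")
        self.holdout_m: Optional[float] = None
        self.holdout_n: int = 0

    # -- local nodal functions (modified Shepard) -----------------------
    @staticmethod
    def _poly_basis(dx: np.ndarray, quadratic: bool) -> np.ndarray:
        """Polynomial features of displacements (no constant term)."""
        cols = [dx]
        if quadratic:
            d = dx.shape[1]
            iu = np.triu_indices(d)
            cols.append(dx[:, iu[0]] * dx[:, iu[1]])
        return np.concatenate(cols, axis=1)

    def _fit_local_models(self):
        """Weighted least-squares nodal model around each training point:
        quadratic when the neighbourhood supports it, else linear."""
        n, d = self.X.shape
        n_quad = d + d * (d + 1) // 2
        quadratic = (n - 1) >= int(1.5 * n_quad)
        n_coef = n_quad if quadratic else d
        k = min(n - 1, max(int(2 * n_coef), 8))
        coefs = np.zeros((n, n_coef))
        for i in range(n):
            dist = np.linalg.norm(self.X - self.X[i], axis=1)
            order = np.argsort(dist)[1:k + 1]
            A = self._poly_basis(self.X[order] - self.X[i], quadratic)
            bvec = self.values[order] - self.values[i]
            wts = 1.0 / np.maximum(dist[order], 1e-12)
            g, *_ = np.linalg.lstsq(A * wts[:, None], bvec * wts,
                                    rcond=None)
            coefs[i] = g
        return coefs, quadratic

    def _weights(self, x: np.ndarray) -> np.ndarray:
        diffs = self.X - x
        dist = np.linalg.norm(diffs, axis=1)
        w = 1.0 / np.maximum(dist, 1e-300) ** self.idw_power
        if self.method == "obtuse-angle" and len(dist) > 1:
            # Shepard's directional correction: node i is down-weighted
            # when another, closer node j lies in nearly the same
            # direction from x (cos of the subtended angle near +1);
            # nodes seen under obtuse angles keep full weight.
            unit = diffs / np.maximum(dist, 1e-300)[:, None]
            cos = unit @ unit.T          # cos of angle subtended by i, j at x
            shadow = ((1.0 - cos) * w[None, :]).sum(axis=1)  # self term is 0
            total = w.sum() - w
            t_i = shadow / np.maximum(total, 1e-300)
            w = w * np.clip(t_i, 1e-6, 2.0) ** 2
        return w

    def _eval_one(self, x: np.ndarray) -> float:
        if len(self.values) == 1:
            return float(self.values[0])
        if self._rbf is not None:
            return float(self._rbf(x[None, :])[0])
        dist = np.linalg.norm(self.X - x, axis=1)
        j = int(np.argmin(dist))
        if dist[j] < 1e-12:
            return float(self.values[j])
        w = self._weights(x)
        if self._planes is not None:
            coefs, quadratic = self._planes
            A = self._poly_basis(x[None, :] - self.X, quadratic)
            nodal = self.values + (A * coefs).sum(axis=1)
        else:
            nodal = self.values
        return float((w * nodal).sum() / w.sum())

    def __call__(self, theta) -> float | np.ndarray:
        if isinstance(theta, ModelParameters):
            theta = theta.as_array()
        theta = np.asarray(theta, dtype=float)
        if theta.ndim == 1:
            x = (theta / self.scale)[self.active]
            return self._eval_one(x)
        return np.array([self((row)) for row in theta])


def fit_surface(samples: Sequence[MetricSample],
                method: str = "obtuse-angle") -> MetricSurface:
    """Build an interpolating surface from evaluated metric samples.

    Duplicate parameter points are dropped with a warning (keeping the
    first occurrence); a single sample yields a constant surface.
    """
    if len(samples) == 0:
        raise ValueError("no samples")
    thetas = np.stack([s.theta.as_array() for s in samples])
    values = np.array([s.zeta2 for s in samples])
    _, keep = np.unique(thetas, axis=0, return_index=True)
    keep = np.sort(keep)
    if len(keep) < len(samples):
        warnings.warn(f"dropped {len(samples) - len(keep)} duplicate "
                      "training points", stacklevel=2)
        thetas, values = thetas[keep], values[keep]
    return MetricSurface(thetas, values, method=method)


def hessian(f: Callable[[np.ndarray], float], x0: np.ndarray,
            rel_step: float = 1e-2, abs_floor: float = 1e-6) -> np.ndarray:
    """Symmetric finite-difference Hessian of a scalar function.

    Diagonal entries use the 5-point central second-difference, mixed
    entries the 4-point cross stencil; the result is symmetrized as
    (H + H^T)/2.  Steps are relative per coordinate (``rel_step *
    |x0_i|``), floored at ``abs_floor`` for zero coordinates.
    """
    x0 = np.asarray(x0, dtype=float)
    d = x0.size
    h = np.maximum(rel_step * np.abs(x0), abs_floor)
    H = np.zeros((d, d))
    f0 = _checked(f, x0, (0, 0))
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        fp, fm = _checked(f, x0 + ei, (i, i)), _checked(f, x0 - ei, (i, i))
        fpp, fmm = _checked(f, x0 + 2 * ei, (i, i)), _checked(f, x0 - 2 * ei, (i, i))
        H[i, i] = (-fpp + 16 * fp - 30 * f0 + 16 * fm - fmm) / (12 * h[i] ** 2)
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            fpp_ = _checked(f, x0 + ei + ej, (i, j))
            fpm = _checked(f, x0 + ei - ej, (i, j))
            fmp = _checked(f, x0 - ei + ej, (i, j))
            fmm_ = _checked(f, x0 - ei - ej, (i, j))
            H[i, j] = H[j, i] = (fpp_ - fpm - fmp + fmm_) / (4 * h[i] * h[j])
    return 0.5 * (H + H.T)


def _checked(f, x, pair):
    v = float(f(x))
    if not np.isfinite(v):
        raise FloatingPointError(
            f"non-finite function value while differencing coordinates {pair}")
    return v


def hessian_at(surface_or_fn, point: ModelParameters,
               names: Sequence[str] | None = None,
               rel_step: float = 1e-2) -> np.ndarray:
    """Hessian of a callable over ModelParameters, restricted to the
    coordinates ``names`` (default: all 27)."""
    names = list(names) if names is not None else list(PARAM_NAMES)
    idx = [PARAM_NAMES.index(n) for n in names]
    theta0 = point.as_array()

    def f(x: np.ndarray) -> float:
        th = theta0.copy()
        th[idx] = x
        arg = th
        if not isinstance(surface_or_fn, MetricSurface):
            arg = ModelParameters.from_array(np.maximum(th, 0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(surface_or_fn(arg))

    return hessian(f, theta0[idx], rel_step=rel_step)


@dataclass
class SloppinessReport:
    """Eigen-structure of a zeta^2 Hessian.

    ``span_orders`` = log10(|lambda_max| / |lambda_min|) measures how many
    decades the sensitivity eigenvalues cover; ``axis_ratio`` =
    sqrt(|lambda_max|/|lambda_min|) is the stiffest-to-sloppiest axis
    length ratio of the deviation ellipsoids.
    """

    hessian: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    normalized_spectrum: np.ndarray
    span_orders: float
    axis_ratio: float
    sloppy: bool
    dimensionality: int
    max_gap_orders: float


def eigen_spectrum(H: np.ndarray, span_threshold: float = 3.0,
                   gap_threshold: float = 3.0,
                   sym_tol: float = 1e-8) -> SloppinessReport:
    """Eigen-decompose a symmetric Hessian and summarise its sloppiness.

    The model is flagged sloppy when the normalized |eigenvalues| span at
    least ``span_threshold`` decades *and* no two consecutive values are
    separated by more than ``gap_threshold`` decades (a sharp gap would
    mark a clean stiff/sloppy split instead of a continuum).
    """
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("Hessian contains non-finite entries")
    asym = np.max(np.abs(H - H.T))
    if asym > sym_tol * max(np.max(np.abs(H)), 1e-300):
        raise ValueError(f"matrix is not symmetric (max asymmetry {asym:g})")
    H = 0.5 * (H + H.T)
    lam, vec = np.linalg.eigh(H)
    order = np.argsort(-np.abs(lam))
    lam, vec = lam[order], vec[:, order]
    mag = np.abs(lam)
    top = mag[0] if mag[0] > 0 else 1.0
    norm = mag / top
    tiny = np.finfo(float).tiny
    span = float(np.log10(top / max(mag[-1], tiny))) if mag[0] > 0 else 0.0
    logs = np.log10(np.maximum(norm, tiny))
    gaps = -np.diff(logs) if len(logs) > 1 else np.array([0.0])
    max_gap = float(np.max(gaps)) if gaps.size else 0.0
    sloppy = span >= span_threshold and max_gap <= gap_threshold
    return SloppinessReport(
        hessian=H, eigenvalues=lam, eigenvectors=vec,
        normalized_spectrum=norm, span_orders=span,
        axis_ratio=float(np.sqrt(top / max(mag[-1], tiny))),
        sloppy=bool(sloppy), dimensionality=H.shape[0],
        max_gap_orders=max_gap)


def validate_surface(surface: MetricSurface,
                     fresh: Sequence[MetricSample]) -> float:
    """Mean relative error of the interpolant against freshly computed
    metric values (the holdout statistic m)."""
    errs = []
    for s in fresh:
        pred = surface(s.theta.as_array())
        denom = abs(s.zeta2)
        if denom == 0:
            continue
        errs.append(abs(pred - s.zeta2) / denom)
    m = float(np.mean(errs)) if errs else float("nan")
    surface.holdout_m = m
    surface.holdout_n = len(errs)
    return m
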