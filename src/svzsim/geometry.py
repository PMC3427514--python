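"""Computational domain: three interconnected boxes (OB, RMS, SVZ).

The migratory path of adult-born neuroblasts is idealised as a chain of
axis-aligned rectangles: a large olfactory-bulb (OB) box, a long thin
rostral-migratory-stream (RMS) channel, and a small subventricular-zone
(SVZ) box.  One model length unit corresponds to 1.4 mm of rodent brain.
All fields live on a cell-centred rectilinear grid covering the union of
the three boxes; a small square at the OB centre marks the region where
arriving neuroblasts either die or mature into neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """Raised for invalid domain specifications (overlap, disconnection)."""


class ResolutionError(ValueError):
    """Raised when the grid spacing cannot resolve the domain."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle [x0, x1) x [y0, y1) in model units."""

    x0: float
    x1: float
    y0: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise GeometryError(f"degenerate box {self}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def centre(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def contains(self, x, y):
        """Half-open membership test (vectorised)."""
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)

    def overlaps(self, other: "Box") -> bool:
        return (self.x0 < other.x1 and other.x0 < self.x1
                and self.y0 < other.y1 and other.y0 < self.y1)

    def touches(self, other: "Box") -> bool:
        """True when the boxes share a finite-length edge segment."""
        share_x = self.x1 == other.x0 or other.x1 == self.x0
        y_olap = min(self.y1, other.y1) - max(self.y0, other.y0)
        share_y = self.y1 == other.y0 or other.y1 == self.y0
        x_olap = min(self.x1, other.x1) - max(self.x0, other.x0)
        return (share_x and y_olap > 0) or (share_y and x_olap > 0)


@dataclass(frozen=True)
class DomainSpec:
    """Geometry of the three-box domain plus grid spacing.

    Defaults reproduce the relative anatomy: a 2x2 OB, a 2-long by
    0.3-wide RMS channel and a 0.6x0.6 SVZ, chained left to right.
    """

    ob_box: Box = field(default_factory=lambda: Box(0.0, 2.0, 0.0, 2.0))
    rms_box: Box = field(default_factory=lambda: Box(2.0, 4.0, 0.85, 1.15))
    svz_box: Box = field(default_factory=lambda: Box(4.0, 4.6, 0.7, 1.3))
    ob_centre: tuple[float, float] = (1.0, 1.0)
    centre_square_side: float = 0.5
    grid_spacing: float = 0.0178
    length_unit_mm: float = 1.4

    def __post_init__(self) -> None:
        boxes = {"ob": self.ob_box, "rms": self.rms_box, "svz": self.svz_box}
        names = list(boxes)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if boxes[a].overlaps(boxes[b]):
                    raise GeometryError(f"{a} and {b} boxes overlap")
        if not self.rms_box.touches(self.ob_box):
            raise GeometryError("RMS does not touch the OB box")
        if not self.rms_box.touches(self.svz_box):
            raise GeometryError("RMS does not touch the SVZ box")
        if self.ob_box.area <= self.svz_box.area:
            raise GeometryError("OB box must be larger than the SVZ box")
        half = 0.5 * self.centre_square_side
        cx, cy = self.ob_centre
        if not (self.ob_box.x0 <= cx - half and cx + half <= self.ob_box.x1
                and self.ob_box.y0 <= cy - half and cy + half <= self.ob_box.y1):
            raise GeometryError("centre square extends outside the OB box")
        if self.grid_spacing <= 0:
            raise ResolutionError("grid spacing must be positive")

    def with_spacing(self, h: float) -> "DomainSpec":
        return DomainSpec(self.ob_box, self.rms_box, self.svz_box,
                          self.ob_centre, self.centre_square_side,
                          h, self.length_unit_mm)


def coarse_spec(h: float = 0.1) -> DomainSpec:
    """Default geometry at reduced resolution, used for desk-scale runs."""
    return DomainSpec().with_spacing(h)


@dataclass
class Grid:
    """Cell-centred grid over the active cells of the three-box union.

    ``nbr`` holds, per direction (W, E, S, N), the active-cell index of
    each cell's lattice neighbour or -1 where the neighbour is outside
    the domain (a zero-flux boundary face).
    """

    xy: np.ndarray              # (n_active, 2) cell-centre coordinates
    h: float
    masks: dict[str, np.ndarray]
    ij: np.ndarray              # (n_active, 2) integer lattice coordinates
    nbr: np.ndarray             # (4, n_active) W,E,S,N neighbour indices
    spec: DomainSpec

    # face arrays, filled at construction: for x-faces L is the west cell
    # and R the east cell; LL/RR the next cells outward (-1 if absent).
    faces_x: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] = None
    faces_y: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] = None

    @property
    def n_active(self) -> int:
        return self.xy.shape[0]

    @property
    def cell_area(self) -> float:
        return self.h * self.h

    def region_of(self) -> np.ndarray:
        lab = np.empty(self.n_active, dtype="U3")
        for name in ("svz", "rms", "ob"):
            lab[self.masks[name]] = name
        return lab

    def trapezoid_weights(self) -> np.ndarray:
        """Weights w_c such that sum(w*u) is the iterated trapezoidal
        integral of u over the domain (x first, then y), honouring the
        row/column segment structure of the box union."""
        n = self.n_active
        wx = np.zeros(n)
        # x-trapezoid within each contiguous run of cells of a row
        for _, idx in _segments(self.ij, axis=0):
            w = np.full(idx.size, self.h)
            if idx.size == 1:
                w[:] = self.h          # isolated cell: midpoint-like
            else:
                w[0] = w[-1] = 0.5 * self.h
            wx[idx] += w
        # y-trapezoid across contiguous runs of rows, per x-column of the
        # row-integral function: the row integral I(y_j) is a 1-D series;
        # weight rows by trapezoid over each run of consecutive j present.
        rows = np.unique(self.ij[:, 1])
        wy = {}
        runs = _consecutive_runs(rows)
        for run in runs:
            for k, j in enumerate(run):
                if len(run) == 1:
                    wy[j] = self.h
                else:
                    wy[j] = 0.5 * self.h if k in (0, len(run) - 1) else self.h
        return wx * np.array([wy[j] for j in self.ij[:, 1]])


def _consecutive_runs(values: np.ndarray) -> list[list[int]]:
    runs: list[list[int]] = []
    for v in values:
        if runs and v == runs[-1][-1] + 1:
            runs[-1].append(int(v))
        else:
            runs.append([int(v)])
    return runs


def _segments(ij: np.ndarray, axis: int):
    """Yield (fixed_coord, active-cell index array) for each contiguous run
    along ``axis`` (0 = runs in x for each row j)."""
    run_coord = ij[:, axis]
    fix_coord = ij[:, 1 - axis]
    order = np.lexsort((run_coord, fix_coord))
    rc, fc = run_coord[order], fix_coord[order]
    start = 0
    for k in range(1, len(order) + 1):
        if (k == len(order) or fc[k] != fc[start]
                or rc[k] != rc[k - 1] + 1):
            yield fc[start], order[start:k]
            start = k


def single_box_grid(box: Box, h: float) -> Grid:
    """Grid over one rectangle (all cells in the 'ob' mask) — a plain
    testbed for the transport operators."""
    spec = DomainSpec.__new__(DomainSpec)   # bypass three-box validation
    object.__setattr__(spec, "ob_box", box)
    object.__setattr__(spec, "rms_box", box)
    object.__setattr__(spec, "svz_box", box)
    object.__setattr__(spec, "ob_centre", box.centre)
    object.__setattr__(spec, "centre_square_side", 0.0)
    object.__setattr__(spec, "grid_spacing", h)
    object.__setattr__(spec, "length_unit_mm", 1.4)
    return _lattice_grid({"ob": box}, h, spec)


def build_grid(spec: DomainSpec) -> Grid:
    """Lay a global lattice of spacing h over the bounding box and keep the
    cells whose centres fall inside the union of the three boxes."""
    h = spec.grid_spacing
    boxes = {"ob": spec.ob_box, "rms": spec.rms_box, "svz": spec.svz_box}
    if spec.rms_box.height < 2 * h - 1e-12:
        raise ResolutionError(
            f"spacing {h} leaves the RMS channel under two cells wide")
    return _lattice_grid(boxes, h, spec)


def _lattice_grid(boxes: dict[str, "Box"], h: float, spec: DomainSpec) -> Grid:
    xmin = min(b.x0 for b in boxes.values())
    ymin = min(b.y0 for b in boxes.values())
    xmax = max(b.x1 for b in boxes.values())
    ymax = max(b.y1 for b in boxes.values())
    ni = int(np.ceil((xmax - xmin) / h - 1e-9))
    nj = int(np.ceil((ymax - ymin) / h - 1e-9))
    ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    xc = xmin + (ii + 0.5) * h
    yc = ymin + (jj + 0.5) * h
    member = {name: box.contains(xc, yc) for name, box in boxes.items()}
    active = np.zeros(ii.size, dtype=bool)
    for name in member:
        active |= member[name]
    idx_of = -np.ones((ni, nj), dtype=np.int64)
    ii_a, jj_a = ii[active], jj[active]
    n = ii_a.size
    idx_of[ii_a, jj_a] = np.arange(n)
    xy = np.column_stack([xc[active], yc[active]])
    masks = {name: member[name][active] for name in ("ob", "rms", "svz")
             if name in member}
    for name in ("ob", "rms", "svz"):
        masks.setdefault(name, np.zeros(n, dtype=bool))
    # resolve any shared-edge double membership by precedence ob > rms > svz
    masks["rms"] &= ~masks["ob"]
    masks["svz"] &= ~(masks["ob"] | masks["rms"])

    half = 0.5 * spec.centre_square_side
    cx, cy = spec.ob_centre
    masks["ob_centre_square"] = masks["ob"] & (
        (np.abs(xy[:, 0] - cx) <= half) & (np.abs(xy[:, 1] - cy) <= half))

    nbr = -np.ones((4, n), dtype=np.int64)
    for d, (di, dj) in enumerate(((-1, 0), (1, 0), (0, -1), (0, 1))):
        pi, pj = ii_a + di, jj_a + dj
        ok = (pi >= 0) & (pi < ni) & (pj >= 0) & (pj < nj)
        nbr[d, ok] = idx_of[pi[ok], pj[ok]]

    # connectivity check across the union
    _check_connected(nbr, n)

    grid = Grid(xy=xy, h=h, masks=masks, ij=np.column_stack([ii_a, jj_a]),
                nbr=nbr, spec=spec)
    grid.faces_x = _faces(nbr, axis=0)
    grid.faces_y = _faces(nbr, axis=1)
    return grid


def _faces(nbr: np.ndarray, axis: int):
    w, e = (0, 1) if axis == 0 else (2, 3)
    L = np.nonzero(nbr[e] >= 0)[0]
    R = nbr[e, L]
    LL = nbr[w, L]
    RR = nbr[e, R]
    return L, R, LL, RR


def _check_connected(nbr: np.ndarray, n: int) -> None:
    if n == 0:
        raise GeometryError("no active cells")
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        c = stack.pop()
        for d in range(4):
            m = nbr[d, c]
            if m >= 0 and not seen[m]:
                seen[m] = True
                stack.append(m)
    if not seen.all():
        raise GeometryError("domain is disconnected at this grid spacing")


def gaussian_field(grid: Grid, centre, amplitude: float, width: float) -> np.ndarray:
    """Isotropic Gaussian a*exp(-|r-c|^2/w^2) sampled at cell centres."""
    if width <= 0:
        raise ValueError("Gaussian width must be positive")
    if amplitude < 0:
        raise ValueError("Gaussian amplitude must be non-negative")
    d2 = ((grid.xy - np.asarray(centre, dtype=float)) ** 2).sum(axis=1)
    return amplitude * np.exp(-d2 / width ** 2)


@dataclass
class AuxiliaryFields:
    """Static scalar fields entering the kinetics.

    q     OB attractant source (Gaussian, amplitude a_1, width a_2)
    g     radial-dispersal factor mature neurons drift against (a_4, a_5)
    eps   apoptosis boost, = d inside the OB-centre square, 0 outside
    zeta  neuron-specification rate, = mu * eps
    """

    q: np.ndarray
    g: np.ndarray
    eps: np.ndarray
    zeta: np.ndarray


def build_aux_fields(grid: Grid, params) -> AuxiliaryFields:
    cx, cy = grid.spec.ob_centre
    q = gaussian_field(grid, (cx, cy), params.a_1, params.a_2)
    g = gaussian_field(grid, (cx, cy), params.a_4, params.a_5)
    half = 0.5 * params.b
    inside = grid.masks["ob"] & (
        (np.abs(grid.xy[:, 0] - cx) <= half)
        & (np.abs(grid.xy[:, 1] - cy) <= half))
    eps = np.where(inside, params.d, 0.0)
    zeta = params.mu * eps
    return AuxiliaryFields(q=q, g=g, eps=eps, zeta=zeta)


def masks_to_table(grid: Grid):
    """Cell table (index, x, y, region) for CSV export."""
    import pandas as pd

    return pd.DataFrame({
        "cell": np.arange(grid.n_active),
        "x": grid.xy[:, 0],
        "y": grid.xy[:, 1],
        "region": grid.region_of(),
    })
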