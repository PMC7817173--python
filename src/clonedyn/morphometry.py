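"""Clone geometry and edge/inner cell classification.

A clone is observed as a set of basal-cell centroids in the plane of the
basal layer (whole-mount projection, micrometre units).  This module
computes per-clone morphometrics — a moment-matched fitted ellipse
(area, perimeter), circularity 4*pi*area/perimeter^2, and basal-cell
density = n_basal / area — and partitions clone cells into *edge* cells
(in contact with at least one cell outside the clone, i.e. along the
clone circumference) and *inner* cells (surrounded entirely by clone
cells).

Contact is defined on a neighbour graph: the Delaunay triangulation of
basal-cell positions with edges longer than ``max_neighbor_dist``
removed (default 15 um, about 1.5 basal-cell diameters).  For clones
recorded without their untransduced surroundings an alternative
``alpha_boundary`` mode labels as edge the cells on the boundary of the
clone's alpha-shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform

from .errors import (
    DegenerateGeometryError,
    EmptySelectionError,
    InvalidInputError,
)
from .fate_stats import Layer

logger = logging.getLogger(__name__)

__all__ = [
    "CellRecord",
    "NeighborGraph",
    "EllipseFit",
    "CloneMorphometrics",
    "build_neighbor_graph",
    "classify_edge_inner",
    "fit_ellipse",
    "circularity",
    "clone_density",
    "clone_morphometrics",
    "morphometry_timecourse",
]

DEFAULT_MAX_NEIGHBOR_DIST = 15.0  # um; ~1.5 basal-cell diameters


@dataclass(frozen=True)
class CellRecord:
    """One basal-layer cell: position, clone membership and marker flags."""

    cell_id: str
    x_um: float
    y_um: float
    layer: str = Layer.BASAL.value
    clone_id: str | None = None  # None/NaN = untransduced neighbour
    genotype: str = "WT"
    animal_id: str = "a1"
    edu: bool = False
    brdu: bool = False
    k10: bool = False


@dataclass
class NeighborGraph:
    """Undirected cell-contact graph with edge lengths in micrometres."""

    cell_ids: np.ndarray  # node labels, in input order
    adjacency: dict  # cell_id -> set of neighbouring cell_ids
    distances: dict  # frozenset({id_a, id_b}) -> centre-to-centre um

    def neighbors(self, cell_id) -> set:
        return self.adjacency.get(cell_id, set())

    @property
    def n_edges(self) -> int:
        return len(self.distances)


def _dedupe_coordinates(
    xy: np.ndarray, on_duplicates: str, rng_seed: int = 0
) -> np.ndarray:
    """Resolve exactly coincident points by deterministic jitter or error."""
    _, inverse, counts = np.unique(
        xy.round(9), axis=0, return_inverse=True, return_counts=True
    )
    if counts.max(initial=0) <= 1:
        return xy
    if on_duplicates == "error":
        dup_row = int(np.flatnonzero(counts[inverse] > 1)[0])
        raise InvalidInputError(
            f"duplicate coordinates at row {dup_row}: {tuple(xy[dup_row])}"
        )
    logger.warning("duplicate coordinates found; applying 1e-6 um deterministic jitter")
    rng = np.random.default_rng(rng_seed)
    jitter = rng.normal(scale=1e-6, size=xy.shape)
    out = xy.copy()
    dup_mask = counts[inverse] > 1
    out[dup_mask] += jitter[dup_mask]
    return out


def build_neighbor_graph(
    cells: pd.DataFrame,
    max_neighbor_dist: float = DEFAULT_MAX_NEIGHBOR_DIST,
    on_duplicates: str = "jitter",
) -> NeighborGraph:
    """Build the basal-cell contact graph.

    Delaunay triangulation of (x_um, y_um) with edges longer than
    ``max_neighbor_dist`` removed.  Fewer than 3 cells, or degenerate
    (collinear) input, falls back to the plain distance-threshold graph.
    Only basal cells participate; suprabasal rows are dropped.
    """
    if max_neighbor_dist <= 0:
        raise InvalidInputError("max_neighbor_dist must be positive")
    df = cells
    if "layer" in df.columns:
        df = df[df["layer"].astype(str).str.lower() == Layer.BASAL.value]
    if len(df) == 0:
        raise EmptySelectionError("no basal cells to build a neighbour graph from")
    ids = df["cell_id"].to_numpy()
    xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
        raise InvalidInputError(f"non-finite coordinates at row {bad}")
    xy = _dedupe_coordinates(xy, on_duplicates)

    pairs: set[tuple[int, int]] = set()
    if len(xy) >= 3:
        try:
            tri = Delaunay(xy)
            for simplex in tri.simplices:
                for a in range(3):
                    i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
                    pairs.add((min(i, j), max(i, j)))
        except QhullError:
            pairs = set()  # collinear input: threshold fallback below
    if not pairs:
        d = squareform(pdist(xy)) if len(xy) > 1 else np.zeros((1, 1))
        for i in range(len(xy)):
            for j in range(i + 1, len(xy)):
                if d[i, j] <= max_neighbor_dist:
                    pairs.add((i, j))

    adjacency: dict = {cid: set() for cid in ids}
    distances: dict = {}
    for i, j in pairs:
        dist = float(np.hypot(*(xy[i] - xy[j])))
        if dist > max_neighbor_dist:
            continue
        adjacency[ids[i]].add(ids[j])
        adjacency[ids[j]].add(ids[i])
        distances[frozenset((ids[i], ids[j]))] = dist
    return NeighborGraph(cell_ids=ids, adjacency=adjacency, distances=distances)


def _alpha_boundary_ids(
    df: pd.DataFrame, alpha: float
) -> set:
    """Cell ids on the boundary of the alpha-shape of the clone's points.

    Alpha-shape = union of Delaunay triangles with circumradius <= alpha;
    boundary edges belong to exactly one retained triangle.  Degenerate
    inputs (fewer than 3 points, collinear) are all boundary.
    """
    ids = df["cell_id"].to_numpy()
    xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(xy) < 3:
        return set(ids)
    try:
        tri = Delaunay(xy)
    except QhullError:
        return set(ids)

    def circumradius(p0, p1, p2) -> float:
        a = np.linalg.norm(p1 - p2)
        b = np.linalg.norm(p0 - p2)
        c = np.linalg.norm(p0 - p1)
        u, v = p1 - p0, p2 - p0
        area2 = abs(u[0] * v[1] - u[1] * v[0])
        if area2 == 0:
            return np.inf
        return a * b * c / (2.0 * area2)

    edge_count: dict[tuple[int, int], int] = {}
    any_kept = False
    for simplex in tri.simplices:
        p = xy[simplex]
        if circumradius(p[0], p[1], p[2]) > alpha:
            continue
        any_kept = True
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            key = (min(i, j), max(i, j))
            edge_count[key] = edge_count.get(key, 0) + 1
    if not any_kept:
        return set(ids)  # too sparse for the alpha-shape: everything is boundary
    boundary_idx = {i for (i, j), c in edge_count.items() if c == 1} | {
        j for (i, j), c in edge_count.items() if c == 1
    }
    return {ids[i] for i in boundary_idx}


def classify_edge_inner(
    cells: pd.DataFrame,
    clone_id,
    graph: NeighborGraph | None = None,
    mode: str = "neighbor_cells",
    max_neighbor_dist: float = DEFAULT_MAX_NEIGHBOR_DIST,
) -> pd.Series:
    """Label each clone basal cell "edge" or "inner".

    ``neighbor_cells`` mode (default, mirrors the wild-type-contact
    definition): a clone cell is *edge* iff it has at least one graph
    neighbour outside the clone — including free space implicitly, since
    an isolated cell has no outside neighbour yet sits on the clone
    circumference; such cells with no neighbours at all are edge.
    ``alpha_boundary`` mode (simulated or isolated clones recorded
    without surroundings): edge iff the cell lies on the boundary of the
    clone's alpha-shape (alpha = ``max_neighbor_dist``).

    Returns a Series indexed by cell_id with values "edge"/"inner".
    """
    df = cells
    if "layer" in df.columns:
        df = df[df["layer"].astype(str).str.lower() == Layer.BASAL.value]
    clone = df[df["clone_id"] == clone_id]
    if len(clone) == 0:
        raise EmptySelectionError(f"clone {clone_id!r} has no basal cells")

    if mode == "alpha_boundary":
        boundary = _alpha_boundary_ids(clone, alpha=max_neighbor_dist)
        labels = {
            cid: ("edge" if cid in boundary else "inner")
            for cid in clone["cell_id"]
        }
    elif mode == "neighbor_cells":
        if graph is None:
            graph = build_neighbor_graph(df, max_neighbor_dist=max_neighbor_dist)
        clone_ids = set(clone["cell_id"])
        missing = clone_ids - set(graph.adjacency)
        if missing:
            raise InvalidInputError(
                f"graph does not cover clone cells: {sorted(missing)[:3]} ..."
            )
        labels = {}
        for cid in clone["cell_id"]:
            nbrs = graph.neighbors(cid)
            outside = nbrs - clone_ids
            labels[cid] = "edge" if (outside or not nbrs) else "inner"
    else:
        raise InvalidInputError(f"unknown edge classification mode {mode!r}")
    return pd.Series(labels, name="edge_inner").loc[clone["cell_id"].to_numpy()]


@dataclass(frozen=True)
class EllipseFit:
    """Moment-matched ellipse: semi-axes a >= b, centre and orientation."""

    area_um2: float
    perimeter_um: float
    a_um: float
    b_um: float
    center: tuple[float, float]
    angle_rad: float


def _ramanujan_perimeter(a: float, b: float) -> float:
    # Ramanujan's second approximation; error < 1e-6 relative for the
    # eccentricities arising from near-circular clones.
    h = ((a - b) / (a + b)) ** 2
    return float(np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h))))


def _polygon_moments(poly: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Signed area, centroid and covariance of a uniform polygonal region."""
    x, y = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-12:
        raise DegenerateGeometryError("polygon has (near-)zero area")
    cx = ((x + x1) * cross).sum() / (6.0 * area)
    cy = ((y + y1) * cross).sum() / (6.0 * area)
    # second moments about the origin, then shift to the centroid
    exx = ((x * x + x * x1 + x1 * x1) * cross).sum() / (12.0 * area)
    eyy = ((y * y + y * y1 + y1 * y1) * cross).sum() / (12.0 * area)
    exy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / (24.0 * area)
    cov = np.array([[exx - cx * cx, exy - cx * cy], [exy - cx * cy, eyy - cy * cy]])
    return abs(float(area)), np.array([cx, cy]), cov


def fit_ellipse(points: np.ndarray, kind: str = "points") -> EllipseFit:
    """Fit the ellipse with the same second moments as the input region.

    ``kind="outline"`` treats the points as an ordered clone outline
    (closed polygon; closure implied) and matches the moments of the
    enclosed region.  ``kind="points"`` treats them as cell centroids
    sampled uniformly from the clone interior and matches the sample
    covariance.  In both cases a uniform ellipse with semi-axes (a, b)
    has covariance eigenvalues (a^2/4, b^2/4), so a = 2*sqrt(lambda_1).
    Area = pi*a*b; perimeter by Ramanujan's second approximation.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be an (n, 2) array")
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 points to fit an ellipse")
    if kind == "outline":
        _, center, cov = _polygon_moments(pts)
    elif kind == "points":
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False, bias=True)
    else:
        raise InvalidInputError(f"unknown input kind {kind!r}")
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * max(evals[1], 1.0):
        raise DegenerateGeometryError("points are collinear; ellipse fit undefined")
    b, a = 2.0 * np.sqrt(evals)  # eigh sorts ascending
    angle = float(np.arctan2(evecs[1, 1], evecs[0, 1]))
    return EllipseFit(
        area_um2=float(np.pi * a * b),
        perimeter_um=_ramanujan_perimeter(float(a), float(b)),
        a_um=float(a),
        b_um=float(b),
        center=(float(center[0]), float(center[1])),
        angle_rad=angle,
    )


def circularity(area_um2: float, perimeter_um: float) -> float:
    """Shape circularity 4*pi*area/perimeter^2 (1 for a circle).

    Values exceeding 1 by numerical noise are capped at 1.
    """
    if area_um2 <= 0 or perimeter_um <= 0:
        raise InvalidInputError("area and perimeter must be positive")
    return min(1.0, 4.0 * np.pi * area_um2 / perimeter_um**2)


def clone_density(n_basal: int, area_um2: float) -> float:
    """Basal-cell packing density: n_basal / clone area, cells per um^2."""
    if area_um2 <= 0:
        raise InvalidInputError("clone area must be positive")
    if n_basal < 1:
        raise InvalidInputError("n_basal must be at least 1")
    return n_basal / area_um2


@dataclass(frozen=True)
class CloneMorphometrics:
    clone_id: str
    n_basal: int
    area_um2: float
    perimeter_um: float
    circularity: float
    density_per_um2: float
    n_edge: int
    n_inner: int

    def __post_init__(self) -> None:
        if self.n_edge + self.n_inner != self.n_basal:
            raise InvalidInputError("edge/inner partition must cover all basal cells")

    @property
    def edge_fraction(self) -> float:
        return self.n_edge / self.n_basal


def clone_morphometrics(
    cells: pd.DataFrame,
    clone_id,
    mode: str = "neighbor_cells",
    max_neighbor_dist: float = DEFAULT_MAX_NEIGHBOR_DIST,
    graph: NeighborGraph | None = None,
) -> CloneMorphometrics:
    """Full per-clone record: fitted-ellipse geometry, density, edge counts."""
    labels = classify_edge_inner(
        cells, clone_id, graph=graph, mode=mode, max_neighbor_dist=max_neighbor_dist
    )
    df = cells[cells["layer"].astype(str).str.lower() == Layer.BASAL.value]
    clone = df[df["clone_id"] == clone_id]
    fit = fit_ellipse(clone[["x_um", "y_um"]].to_numpy(dtype=float), kind="points")
    return CloneMorphometrics(
        clone_id=str(clone_id),
        n_basal=len(clone),
        area_um2=fit.area_um2,
        perimeter_um=fit.perimeter_um,
        circularity=circularity(fit.area_um2, fit.perimeter_um),
        density_per_um2=clone_density(len(clone), fit.area_um2),
        n_edge=int((labels == "edge").sum()),
        n_inner=int((labels == "inner").sum()),
    )


def morphometry_timecourse(
    cells: pd.DataFrame,
    mode: str = "neighbor_cells",
    max_neighbor_dist: float = DEFAULT_MAX_NEIGHBOR_DIST,
) -> pd.DataFrame:
    """Per-clone morphometrics for every (week, clone) in a cell table.

    ``cells`` must carry a ``week`` column; clones with fewer than 3
    basal cells are reported with NaN geometry (their edge counts are
    still valid: every cell is edge).  Weeks with no clones are skipped
    with a logged warning.
    """
    if "week" not in cells.columns:
        raise InvalidInputError("timecourse requires a 'week' column")
    rows = []
    for week, tab in cells.groupby("week"):
        basal = tab[tab["layer"].astype(str).str.lower() == Layer.BASAL.value]
        # empty-string clone ids mark untransduced background cells
        clone_ids = sorted(
            c for c in basal["clone_id"].dropna().unique() if str(c) != ""
        )
        if not clone_ids:
            logger.warning("week %s: no clones found", week)
            continue
        for cid in clone_ids:
            clone = basal[basal["clone_id"] == cid]
            labels = classify_edge_inner(
                tab, cid, mode=mode, max_neighbor_dist=max_neighbor_dist
            )
            n_edge = int((labels == "edge").sum())
            row = {
                "week": week,
                "clone_id": cid,
                "n_basal": len(clone),
                "n_edge": n_edge,
                "n_inner": len(clone) - n_edge,
                "edge_fraction": n_edge / len(clone),
            }
            try:
                fit = fit_ellipse(
                    clone[["x_um", "y_um"]].to_numpy(dtype=float), kind="points"
                )
                row.update(
                    area_um2=fit.area_um2,
                    perimeter_um=fit.perimeter_um,
                    circularity=circularity(fit.area_um2, fit.perimeter_um),
                    density_per_um2=clone_density(len(clone), fit.area_um2),
                )
            except DegenerateGeometryError:
                row.update(
                    area_um2=np.nan,
                    perimeter_um=np.nan,
                    circularity=np.nan,
                    density_per_um2=np.nan,
                )
            rows.append(row)
    return pd.DataFrame(rows)
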