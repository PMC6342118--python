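"""Landscape-resistance models: rasterized cost surfaces, least-cost
distances, and isolation-by-resistance variation partitioning.

A :class:`ResistanceSurface` is a regular grid of per-cell traversal costs
(background exactly 1).  Vector features (roads as buffered lines, water
and fire polygons) are burned in at a cost value; overlapping layers take
the maximum cost.  Least-cost distances between sample points are shortest
paths on the 8-connected cell graph with edge weight = mean endpoint cost x
cell size (x sqrt(2) for diagonals).

``mg_landscape`` partitions the spatially explained genetic variation into
a landscape-specific fraction [a], a coordinate-specific fraction [c], their
confounded overlap [b] and a residual [d], by forward-selecting MEM
eigenvectors from the least-cost and straight-line distance matrices and
running two-block variation partitioning.  ``model_search`` screens the
univariate feature x cost grid and the combined models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import shape

from .genotypes import GenotypeTable
from .mem import (
    dps_distance,
    forward_select,
    mem_basis,
    pcoa,
)
from .varpart import VariationPartition, variation_partition

__all__ = [
    "GridSpec",
    "ResistanceSurface",
    "LandscapeModel",
    "load_features",
    "rasterize_features",
    "build_surface",
    "cost_distance_matrix",
    "mg_landscape",
    "model_search",
]

FIRE_YEARS = (1964, 2013)   # only recent burns count as resistance
ROAD_BUFFER_M = 500.0       # buffer radius applied to road lines
COST_GRID = (10, 50, 100)   # screened per-feature cost values


@dataclass
class GridSpec:
    """Regular grid: origin at the lower-left corner, row 0 = southmost."""

    x0: float
    y0: float
    cell_size: float
    n_rows: int
    n_cols: int

    @classmethod
    def from_points(
        cls, xy: np.ndarray, cell_size: float | None = None, margin_cells: int = 2
    ) -> "GridSpec":
        xy = np.asarray(xy, float)
        xmin, ymin = xy.min(axis=0)
        xmax, ymax = xy.max(axis=0)
        if cell_size is None:
            cell_size = max(xmax - xmin, ymax - ymin) / 200.0
        if cell_size <= 0:
            raise ValueError("cell_size must be positive")
        x0 = xmin - margin_cells * cell_size
        y0 = ymin - margin_cells * cell_size
        n_cols = int(np.ceil((xmax - x0) / cell_size)) + margin_cells
        n_rows = int(np.ceil((ymax - y0) / cell_size)) + margin_cells
        return cls(x0=x0, y0=y0, cell_size=cell_size, n_rows=n_rows, n_cols=n_cols)

    def cell_centers(self):
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def cell_of(self, xy: np.ndarray) -> np.ndarray:
        """(row, col) of each point; raises if any point falls off-grid."""
        xy = np.asarray(xy, float)
        col = np.floor((xy[:, 0] - self.x0) / self.cell_size).astype(int)
        row = np.floor((xy[:, 1] - self.y0) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if bad.any():
            raise ValueError(f"points outside grid at indices {np.flatnonzero(bad)}")
        return np.column_stack([row, col])


@dataclass
class ResistanceSurface:
    """Per-cell traversal costs; background is exactly 1."""

    cost: np.ndarray                 # (n_rows, n_cols), >= 1 (inf allowed)
    grid: GridSpec
    crs: str = "projected-m"
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.cost = np.asarray(self.cost, dtype=float)
        if self.cost.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("cost array does not match grid shape")
        if np.any(self.cost < 1):
            raise ValueError("cell costs must be >= 1")

    @classmethod
    def flat(cls, grid: GridSpec) -> "ResistanceSurface":
        """Uniform cost-1 surface: the pure isolation-by-distance model."""
        return cls(cost=np.ones((grid.n_rows, grid.n_cols)), grid=grid,
                   provenance=[("flat", 1)])

    def to_ascii_grid(self, path) -> None:
        """ESRI ASCII grid export (text raster)."""
        g = self.grid
        header = (
            f"ncols {g.n_cols}\nnrows {g.n_rows}\n"
            f"xllcorner {g.x0}\nyllcorner {g.y0}\n"
            f"cellsize {g.cell_size}\nNODATA_value -9999\n"
        )
        body = "\n".join(
            " ".join(f"{v:g}" for v in row) for row in self.cost[::-1]
        )
        Path(path).write_text(header + body + "\n", encoding="utf-8")


@dataclass
class LandscapeModel:
    """Named set of (feature class, cost) layers over a shared grid."""

    name: str
    layers: list          # [(feature_class, cost), ...]
    surface: ResistanceSurface


# ---------------------------------------------------------------------------
# Vector features and rasterization
# ---------------------------------------------------------------------------


def load_features(path_or_obj) -> list[tuple]:
    """Load a GeoJSON FeatureCollection into (geometry, properties) pairs.

    Features carry properties ``class`` in {roads, water, fire} and, for
    fire polygons, ``year`` (ignition year).
    """
    if isinstance(path_or_obj, (str, Path)):
        obj = json.loads(Path(path_or_obj).read_text(encoding="utf-8"))
    else:
        obj = path_or_obj
    feats = []
    for f in obj.get("features", []):
        feats.append((shape(f["geometry"]), dict(f.get("properties") or {})))
    return feats


def rasterize_features(
    features: list[tuple],
    cost: float,
    grid: GridSpec,
    surface: ResistanceSurface | None = None,
    feature_class: str | None = None,
    road_buffer: float = ROAD_BUFFER_M,
    fire_years: tuple[int, int] = FIRE_YEARS,
) -> ResistanceSurface:
    """Burn vector features into a resistance surface at a cost value.

    Line features of class 'roads' are buffered by ``road_buffer`` meters
    (radius); fire polygons are kept only when their ignition year lies in
    ``fire_years`` (inclusive).  Cells are burned by center containment;
    overlaps take the maximum cost.
    """
    if surface is None:
        surface = ResistanceSurface.flat(grid)
    geoms = []
    for geom, props in features:
        cls = props.get("class", feature_class)
        if feature_class is not None and cls != feature_class:
            continue
        if cls == "fire":
            year = props.get("year")
            if year is None or not (fire_years[0] <= year <= fire_years[1]):
                continue
        if cls == "roads" or geom.geom_type in ("LineString", "MultiLineString"):
            geom = geom.buffer(road_buffer)
        geoms.append(geom)
    if not geoms:
        return surface
    union = shapely.union_all(geoms)
    xs, ys = grid.cell_centers()
    XX, YY = np.meshgrid(xs, ys)
    mask = shapely.contains_xy(union, XX.ravel(), YY.ravel()).reshape(XX.shape)
    # boundary cells: center-containment is open on the boundary; include
    # centers exactly on it via intersects of a point check only when needed
    cost_arr = surface.cost.copy()
    cost_arr[mask] = np.maximum(cost_arr[mask], cost)
    prov = surface.provenance + [(feature_class or "features", cost)]
    return ResistanceSurface(cost=cost_arr, grid=grid, crs=surface.crs,
                             provenance=prov)


def build_surface(
    features: list[tuple],
    layers: list[tuple],
    grid: GridSpec,
    **kwargs,
) -> ResistanceSurface:
    """Stack several (feature_class, cost) layers with the max-cost rule."""
    surf = ResistanceSurface.flat(grid)
    for cls, cost in layers:
        surf = rasterize_features(
            features, cost, grid, surface=surf, feature_class=cls, **kwargs
        )
    return surf


# ---------------------------------------------------------------------------
# Least-cost distances
# ---------------------------------------------------------------------------

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
# knight moves for the 16-direction graph; each passes through two
# intermediate cells that must share the traversal cost, otherwise a cheap
# jump could skip straight over a narrow high-cost corridor
_KNIGHT = [(-2, -1), (-2, 1), (-1, -2), (-1, 2), (1, -2), (1, 2), (2, -1), (2, 1)]


def cost_distance_matrix(
    surface: ResistanceSurface, points: np.ndarray, connectivity: int = 8
) -> np.ndarray:
    """Least-cost-path distances between sample points over a cost surface.

    The cell graph is 8-connected by default; an edge between cells i, j
    costs (cost_i + cost_j)/2 x cell size, times sqrt(2) for diagonal
    moves.  ``connectivity=16`` adds knight moves (weighted over the two
    traversed intermediate cells as well), reducing the worst-case metric
    distortion of the grid approximation from ~8% to ~3%.  Points map to
    the cell containing them; coincident cells give 0.
    """
    if connectivity not in (8, 16):
        raise ValueError("connectivity must be 8 or 16")
    grid = surface.grid
    rc = grid.cell_of(points)
    nodes = rc[:, 0] * grid.n_cols + rc[:, 1]
    R, C = grid.n_rows, grid.n_cols
    cost = surface.cost
    finite = np.isfinite(cost)
    rows_idx, cols_idx, weights = [], [], []
    cs = grid.cell_size
    offsets = _OFFSETS + (_KNIGHT if connectivity == 16 else [])
    for dr, dc in offsets:
        r0 = slice(max(0, -dr), R - max(0, dr))
        r1 = slice(max(0, dr), R - max(0, -dr))
        c0 = slice(max(0, -dc), C - max(0, dc))
        c1 = slice(max(0, dc), C - max(0, -dc))
        knight = abs(dr) + abs(dc) == 3
        if knight:
            # intermediate cells of the knight segment
            m1 = (np.sign(dr) * (abs(dr) > 1), np.sign(dc) * (abs(dc) > 1))
            m2 = (dr - np.sign(dr) * (abs(dr) > 1), dc - np.sign(dc) * (abs(dc) > 1))

            def shift(delta):
                ddr, ddc = int(delta[0]), int(delta[1])
                rr0 = slice(r0.start + ddr, r0.stop + ddr)
                cc0 = slice(c0.start + ddc, c0.stop + ddc)
                return cost[rr0, cc0]

            w = 0.25 * (cost[r0, c0] + cost[r1, c1] + shift(m1) + shift(m2))
            w = w * cs * np.sqrt(5.0)
            ok = (
                finite[r0, c0] & finite[r1, c1]
                & np.isfinite(shift(m1)) & np.isfinite(shift(m2))
            )
        else:
            w = 0.5 * (cost[r0, c0] + cost[r1, c1]) * cs
            if dr and dc:
                w = w * np.sqrt(2.0)
            ok = finite[r0, c0] & finite[r1, c1]
        rr, cc = np.meshgrid(
            np.arange(R)[r0], np.arange(C)[c0], indexing="ij"
        )
        src = (rr * C + cc)[ok]
        dst = ((rr + dr) * C + (cc + dc))[ok]
        rows_idx.append(src)
        cols_idx.append(dst)
        weights.append(w[ok])
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows_idx), np.concatenate(cols_idx))),
        shape=(R * C, R * C),
    ).tocsr()
    uniq, inv = np.unique(nodes, return_inverse=True)
    dist = dijkstra(graph, directed=False, indices=uniq)
    D = dist[inv][:, nodes]
    if np.isinf(D).any():
        bad = np.argwhere(np.isinf(D))[:3]
        raise ValueError(f"disconnected point pairs (least-cost): {bad.tolist()}")
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# IBR variation partitioning
# ---------------------------------------------------------------------------


def _select_block(Y, D, alpha, n_perm, rng, source) -> np.ndarray:
    """Forward-selected MEM design matrix from a spatial distance matrix."""
    basis = mem_basis(D, source=source)
    sel_p = forward_select(Y, basis, "positive", alpha, n_perm, rng)
    sel_n = forward_select(Y, basis, "negative", alpha, n_perm, rng)
    sel = np.concatenate([sel_p, sel_n]).astype(int)
    return basis.vectors[:, sel] if sel.size else np.empty((Y.shape[0], 0))


def mg_landscape(
    table: GenotypeTable,
    xy: np.ndarray | None = None,
    model: LandscapeModel | None = None,
    alpha: float = 0.05,
    n_perm: int = 1000,
    n_perm_part: int | None = None,
    random_state=None,
    response: np.ndarray | None = None,
    connectivity: int = 16,
) -> VariationPartition:
    """Partition spatial genetic variation into landscape vs coordinate parts.

    X1 = MEM eigenvectors forward-selected from least-cost distances under
    the landscape model; X2 = MEM eigenvectors forward-selected from
    straight-line distances; response Y = principal coordinates of the Dps
    genetic distance (or ``response`` if given).  Fractions follow the
    adjusted-R² algebra: [a] landscape-specific, [c] coordinate-specific,
    [b] confounded, [d] residual.

    ``n_perm`` drives forward selection; ``n_perm_part`` (default: same)
    drives the partition p-values — pass 0 to skip them.  The least-cost
    graph defaults to 16 directions here (lower metric distortion of the
    grid approximation, so a flat surface partitions like plain distance);
    pass ``connectivity=8`` for the classical rook+diagonal graph.
    """
    if xy is None:
        xy = table.xy
    xy = np.asarray(xy, float)
    rng = np.random.default_rng(random_state)
    if response is None:
        Y, _ = pcoa(dps_distance(table))
    else:
        Y = np.asarray(response, float)
    Y = Y - Y.mean(axis=0)
    D_geo = squareform(pdist(xy))
    if np.all(model.surface.cost == 1.0):
        # a uniform surface IS the straight-line IBD model: its least-cost
        # distance is exactly Euclidean, so skip the grid approximation
        D_cost = D_geo
    else:
        D_cost = cost_distance_matrix(
            model.surface, xy, connectivity=connectivity
        )
    X1 = _select_block(Y, D_cost, alpha, n_perm, rng, "cost")
    X2 = _select_block(Y, D_geo, alpha, n_perm, rng, "euclidean")
    npp = n_perm if n_perm_part is None else n_perm_part
    return variation_partition(
        Y, X1, X2, n_perm=npp, random_state=rng,
        label_1=model.name, label_2="coordinates",
    )


def model_search(
    table: GenotypeTable,
    xy: np.ndarray,
    features: list[tuple],
    grid: GridSpec | None = None,
    costs=COST_GRID,
    alpha: float = 0.05,
    n_perm: int = 1000,
    n_perm_part: int | None = None,
    random_state=None,
    rank_by: str = "a",
    **raster_kwargs,
) -> pd.DataFrame:
    """Two-stage landscape model screen.

    Stage 1 tests each feature class (roads, water, fire) univariately at
    each cost value and keeps, per feature, the cost maximizing the
    landscape-specific fraction [a] (or [abc] with ``rank_by='abc'``).
    Stage 2 runs the four combined models at the kept costs plus the flat
    (pure-IBD) surface.  Returns a results table with one row per model.
    """
    xy = np.asarray(xy, float)
    if grid is None:
        grid = GridSpec.from_points(xy)
    rng = np.random.default_rng(random_state)
    Y, _ = pcoa(dps_distance(table))
    classes = [c for c in ("roads", "water", "fire")
               if any(p.get("class") == c for _, p in features)]
    if not classes:
        raise ValueError("no recognized feature classes in input")

    def run(name, layers):
        surf = build_surface(features, layers, grid, **raster_kwargs)
        part = mg_landscape(
            table, xy, LandscapeModel(name, layers, surf),
            alpha=alpha, n_perm=n_perm, n_perm_part=n_perm_part,
            random_state=rng, response=Y,
        )
        row = {"model": name, **part.as_row()}
        return row, part

    rows = []
    flat_row, _ = run("IBD", [])
    rows.append(flat_row)
    best_cost = {}
    for cls in classes:
        best_val, best_c = -np.inf, None
        for cost in costs:
            row, part = run(f"{cls} ({cost})", [(cls, cost)])
            rows.append(row)
            crit = part.a if rank_by == "a" else part.abc
            if crit > best_val:
                best_val, best_c = crit, cost
        best_cost[cls] = best_c
    combos = []
    if len(classes) >= 2:
        from itertools import combinations

        for r in range(2, len(classes) + 1):
            combos.extend(combinations(classes, r))
    for combo in combos:
        name = " and ".join(combo)
        layers = [(c, best_cost[c]) for c in combo]
        row, _ = run(name, layers)
        rows.append(row)
    return pd.DataFrame(rows)
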