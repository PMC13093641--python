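"""Landscape-resistance and environmental-distance machinery.

Builds a movement-cost surface from slope and land-use rasters with fixed
reclassification tables, computes least-cost-path distances between sampling
sites (Dijkstra on the 8-connected cell lattice), great-circle distances,
environmental dissimilarity from bioclim-style tables, and the greedy
|r| > 0.7 collinearity filter that keeps, from each correlated variable
pair, the one more associated with genetic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import pdist, squareform

from .stats import DistanceMatrix

__all__ = [
    "Raster",
    "ResistanceConfig",
    "slope_resistance",
    "landuse_resistance",
    "combine_resistance",
    "least_cost_distance",
    "great_circle_distance",
    "env_dissimilarity",
    "select_uncorrelated_vars",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class Raster:
    """Rectangular grid with an ESRI-ASCII-style georeference.

    ``origin`` is the (x, y) of the lower-left corner; row 0 of ``values``
    is the TOP row, as in the .asc format. ``cell_size`` is in meters (a
    planar lattice approximation is used inside rasters).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def shape(self):
        return self.values.shape

    def nodata_mask(self) -> np.ndarray:
        return (self.values == self.nodata) | ~np.isfinite(self.values)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y)."""
        nrow = self.values.shape[0]
        col = int((x - self.origin[0]) // self.cell_size)
        row_from_bottom = int((y - self.origin[1]) // self.cell_size)
        row = nrow - 1 - row_from_bottom
        if not (0 <= row < nrow and 0 <= col < self.values.shape[1]):
            raise ValueError(f"point ({x}, {y}) outside raster")
        return row, col

    # ESRI ASCII grid (.asc), 6-line header + rows top-down
    def to_ascii(self, path) -> None:
        r, c = self.shape
        with Path(path).open("w") as fh:
            fh.write(f"ncols {c}\nnrows {r}\n")
            fh.write(f"xllcorner {self.origin[0]:.8g}\n"
                     f"yllcorner {self.origin[1]:.8g}\n")
            fh.write(f"cellsize {self.cell_size:.8g}\n")
            fh.write(f"NODATA_value {self.nodata:.8g}\n")
            for row in self.values:
                fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")

    @classmethod
    def from_ascii(cls, path) -> "Raster":
        lines = Path(path).read_text().strip().split("\n")
        hdr = {}
        i = 0
        while i < len(lines):
            parts = lines[i].split()
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "nodata_value"):
                hdr[parts[0].lower()] = float(parts[1])
                i += 1
            else:
                break
        vals = np.array([[float(v) for v in ln.split()] for ln in lines[i:]])
        if vals.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
            raise ValueError("ASCII grid body does not match header")
        return cls(vals, hdr["cellsize"],
                   (hdr.get("xllcorner", 0.0), hdr.get("yllcorner", 0.0)),
                   hdr.get("nodata_value", -9999.0))


#: Default land-use class codes used by the synthetic rasters.
DEFAULT_LANDUSE_CODES = {1: "Forest", 2: "Grassland", 3: "Bare",
                         4: "Agricultural", 5: "InlandWater", 6: "BuiltUp"}


@dataclass
class ResistanceConfig:
    """Reclassification tables for slope and land use.

    Slope (degrees) maps through a right-continuous step function on the
    stated band edges: <=10 -> 1, <=40 -> 1.5, <=60 -> 4, <=80 -> 6,
    above -> 10 (gaps between published bands take the next band's value).
    Land-use resistances: Forest 1, Grassland 2, Bare 2, Agricultural 3,
    InlandWater 5, BuiltUp 10.
    """

    slope_breaks: tuple = ((10.0, 1.0), (40.0, 1.5), (60.0, 4.0),
                           (80.0, 6.0))
    slope_above: float = 10.0
    landuse_table: dict = field(default_factory=lambda: {
        "Forest": 1.0, "Grassland": 2.0, "Bare": 2.0, "Agricultural": 3.0,
        "InlandWater": 5.0, "BuiltUp": 10.0})
    landuse_codes: dict = field(
        default_factory=lambda: dict(DEFAULT_LANDUSE_CODES))
    combine_rule: str = "product"

    def __post_init__(self) -> None:
        edges = [e for e, _ in self.slope_breaks]
        if edges != sorted(edges):
            raise ValueError("slope break edges must increase")
        if min(v for _, v in self.slope_breaks) < 1 or self.slope_above < 1:
            raise ValueError("resistances must be >= 1")


def slope_resistance(slope_deg: Raster,
                     cfg: ResistanceConfig | None = None) -> Raster:
    """Reclassify a slope raster (degrees, 0-90) to resistance values."""
    cfg = cfg or ResistanceConfig()
    v = slope_deg.values
    mask = slope_deg.nodata_mask()
    valid = v[~mask]
    if valid.size and (valid.min() < 0 or valid.max() > 90):
        raise ValueError("slope values must lie in [0, 90] degrees")
    out = np.full_like(v, cfg.slope_above)
    for edge, res in reversed(cfg.slope_breaks):
        out[v <= edge] = res
    out[mask] = slope_deg.nodata
    return Raster(out, slope_deg.cell_size, slope_deg.origin,
                  slope_deg.nodata)


def landuse_resistance(classes: Raster,
                       cfg: ResistanceConfig | None = None) -> Raster:
    """Map integer land-use class codes to resistance values."""
    cfg = cfg or ResistanceConfig()
    v = classes.values
    mask = classes.nodata_mask()
    out = np.full_like(v, classes.nodata)
    codes = np.unique(v[~mask]).astype(int)
    for code in codes:
        name = cfg.landuse_codes.get(int(code))
        if name is None or name not in cfg.landuse_table:
            raise ValueError(f"unmapped land-use code {code}")
        out[v == code] = cfg.landuse_table[name]
    out[mask] = classes.nodata
    return Raster(out, classes.cell_size, classes.origin, classes.nodata)


def combine_resistance(slope_r: Raster, landuse_r: Raster,
                       rule: str = "product") -> Raster:
    """Combine the two resistance layers cell-wise (product by default;
    independent impedances multiply). Nodata propagates."""
    if slope_r.shape != landuse_r.shape or \
            slope_r.cell_size != landuse_r.cell_size:
        raise ValueError("resistance grids are not aligned")
    a, b = slope_r.values, landuse_r.values
    if rule == "product":
        out = a * b
    elif rule == "sum":
        out = a + b
    elif rule == "max":
        out = np.maximum(a, b)
    else:
        raise ValueError(f"unknown combine rule {rule!r}")
    bad = slope_r.nodata_mask() | landuse_r.nodata_mask()
    out[bad] = slope_r.nodata
    return Raster(out, slope_r.cell_size, slope_r.origin, slope_r.nodata)


def _lattice_graph(resistance: Raster):
    """Sparse 8-connected lattice; edge weight = mean cell resistance x
    cell_size (x sqrt(2) on diagonals). Nodata cells are disconnected."""
    v = resistance.values
    nrow, ncol = v.shape
    bad = resistance.nodata_mask()
    idx = np.arange(nrow * ncol).reshape(nrow, ncol)
    rows, cols, wts = [], [], []
    steps = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)),
             (1, -1, np.sqrt(2))]
    for dr, dc, fac in steps:
        r0 = slice(0, nrow - dr)
        r1 = slice(dr, nrow)
        if dc >= 0:
            c0, c1 = slice(0, ncol - dc), slice(dc, ncol)
        else:
            c0, c1 = slice(-dc, ncol), slice(0, ncol + dc)
        a = idx[r0, c0].ravel()
        b = idx[r1, c1].ravel()
        ok = ~(bad[r0, c0].ravel() | bad[r1, c1].ravel())
        w = (0.5 * (v[r0, c0].ravel() + v[r1, c1].ravel())
             * resistance.cell_size * fac)
        rows.append(a[ok])
        cols.append(b[ok])
        wts.append(w[ok])
    n = nrow * ncol
    return coo_matrix((np.concatenate(wts),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n)).tocsr()


def least_cost_distance(resistance: Raster, points, labels=None
                        ) -> DistanceMatrix:
    """Least-cost-path distances between points over a resistance surface.

    ``points`` are (x, y) planar coordinates inside the raster (or
    (row, col) tuples via ``cells=True`` semantics when given as int pairs).
    Dijkstra on the 8-connected lattice; an unreachable pair is an error.
    """
    cells = []
    for p in points:
        if isinstance(p[0], (int, np.integer)) and \
                isinstance(p[1], (int, np.integer)):
            cells.append((int(p[0]), int(p[1])))
        else:
            cells.append(resistance.cell_of(float(p[0]), float(p[1])))
    bad = resistance.nodata_mask()
    for (r, c) in cells:
        if bad[r, c]:
            raise ValueError(f"point at cell ({r}, {c}) lies on nodata")
    graph = _lattice_graph(resistance)
    ncol = resistance.shape[1]
    nodes = [r * ncol + c for r, c in cells]
    dist = dijkstra(graph, directed=False, indices=nodes)
    n = len(nodes)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, nodes[j]]
            if not np.isfinite(d):
                raise ValueError(f"points {i} and {j} are not connected")
            out[i, j] = out[j, i] = d
    labels = list(labels) if labels is not None else \
        [f"p{i}" for i in range(n)]
    return DistanceMatrix(labels, out, kind="cost")


def great_circle_distance(points, labels=None) -> DistanceMatrix:
    """Haversine distances (meters) between (lon, lat) degree pairs."""
    pts = np.asarray(points, dtype=np.float64)
    lon = np.radians(pts[:, 0])
    lat = np.radians(pts[:, 1])
    if (np.abs(pts[:, 1]) > 90).any() or (np.abs(pts[:, 0]) > 180).any():
        raise ValueError("coordinates out of range")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :]
         * np.sin(dlon / 2) ** 2)
    d = 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    labels = list(labels) if labels is not None else \
        [f"p{i}" for i in range(len(pts))]
    return DistanceMatrix(labels, d, kind="geographic")


def env_dissimilarity(climate, variables=None, metric: str = "braycurtis"
                      ) -> DistanceMatrix:
    """Pairwise environmental dissimilarity between sites.

    ``climate`` is a DataFrame indexed by site with one column per
    variable. Variables are min-max scaled for the Bray-Curtis default
    (which requires non-negative input) and z-scored for Euclidean;
    constant variables are dropped with a warning.
    """
    import warnings

    df = climate[list(variables)] if variables is not None else climate
    if df.shape[1] < 1:
        raise ValueError("need at least one variable")
    X = df.to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(df.columns, keep) if not k]
        warnings.warn(f"dropping constant variable(s): {dropped}")
        X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("all variables constant")
    if metric == "braycurtis":
        X = (X - X.min(axis=0)) / (X.max(axis=0) - X.min(axis=0))
        d = squareform(pdist(X, metric="braycurtis"))
    elif metric == "euclidean":
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        d = squareform(pdist(X, metric="euclidean"))
    else:
        raise ValueError(f"unsupported metric {metric!r}")
    return DistanceMatrix([str(i) for i in df.index], d,
                          kind="environmental")


def select_uncorrelated_vars(climate, genetic_dist: DistanceMatrix,
                             r_max: float = 0.7,
                             metric: str = "euclidean") -> list[str]:
    """Greedy collinearity filter over climate variables.

    While any variable pair has Pearson |r| above ``r_max``, drop from the
    most-correlated pair the variable whose single-variable environmental
    distance correlates less (Mantel-style lower-triangle Pearson r) with
    the genetic distance matrix.
    """
    if climate.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    cols = list(climate.columns)
    iu = np.triu_indices(len(genetic_dist.labels), k=1)
    gvec = genetic_dist.values[iu]

    def gen_assoc(col) -> float:
        x = climate[col].to_numpy(dtype=float)
        dmat = np.abs(x[:, None] - x[None, :])[iu]
        if dmat.std() == 0 or gvec.std() == 0:
            return 0.0
        return abs(np.corrcoef(dmat, gvec)[0, 1])

    assoc = {c: gen_assoc(c) for c in cols}
    while len(cols) > 1:
        sub = climate[cols].to_numpy(dtype=float)
        r = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(r, 0.0)
        i, j = np.unravel_index(np.abs(r).argmax(), r.shape)
        if abs(r[i, j]) <= r_max:
            break
        drop = cols[i] if assoc[cols[i]] < assoc[cols[j]] else cols[j]
        cols.remove(drop)
    return cols
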