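"""Least-cost "coastal" distances over a bathymetry raster.

Sites on a coastline are connected through water only: movement is
restricted to raster cells whose depth lies in a navigable band (e.g.
0-30 m, approximating along-shore larval transport), and the distance
between two sites is the shortest 8-connected path through navigable
cells with great-circle edge weights. Per-site maximum-depth overrides
relax the band for whole paths terminating at that site (e.g. to cross a
deep channel separating an island site from the mainland shelf).

Depth convention: metres positive down; cells with depth <= 0 are land
and never navigable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

EARTH_RADIUS_KM = 6371.0088


class UnreachableError(RuntimeError):
    pass


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km between two WGS84 points."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


@dataclass
class BathymetryGrid:
    """Regular lat/lon lattice of depths (m, positive down; land <= 0)."""

    lats: np.ndarray   # (nrow,) cell-centre latitudes, increasing
    lons: np.ndarray   # (ncol,) cell-centre longitudes, increasing
    depth: np.ndarray  # (nrow, ncol)

    def __post_init__(self):
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.lats), len(self.lons)):
            raise ValueError("depth shape does not match lattice")
        if len(self.lats) > 1 and not np.all(np.diff(self.lats) > 0):
            raise ValueError("latitudes must be increasing")
        if len(self.lons) > 1 and not np.all(np.diff(self.lons) > 0):
            raise ValueError("longitudes must be increasing")

    @property
    def shape(self):
        return self.depth.shape

    def save(self, path) -> str:
        header = {"lats": self.lats.tolist(), "lons": self.lons.tolist()}
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            np.savetxt(fh, self.depth, fmt="%.3f")
        return str(path)

    @classmethod
    def load(cls, path) -> "BathymetryGrid":
        with open(path) as fh:
            header = json.loads(fh.readline())
            depth = np.loadtxt(fh, ndmin=2)
        return cls(np.array(header["lats"]), np.array(header["lons"]), depth)


@dataclass
class DepthPolicy:
    """Navigable depth band with per-site maximum-depth relaxations."""

    min_depth: float = 0.0
    max_depth: float = 30.0
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.min_depth >= self.max_depth:
            raise ValueError("min_depth must be < max_depth")
        for site, v in self.overrides.items():
            if v < self.max_depth:
                raise ValueError(f"override for {site!r} must be >= global max_depth")

    def max_for(self, site_code: str | None) -> float:
        if site_code is not None and site_code in self.overrides:
            return self.overrides[site_code]
        return self.max_depth


def make_synthetic_bathymetry(spec: dict) -> BathymetryGrid:
    """Deterministic fixture grids: a base depth plus box features.

    ``spec`` keys: ``lat0, lat1, lon0, lon1`` bounds, ``nrow, ncol``,
    ``depth`` (base, default 20), and ``features`` — a list of
    ``{"type": "land"|"set_depth", "box": [r0, r1, c0, c1], "depth": d}``
    boxes in row/column index space (``r1``/``c1`` exclusive). Land boxes
    set depth to 0.
    """
    nrow, ncol = int(spec["nrow"]), int(spec["ncol"])
    lats = np.linspace(spec.get("lat0", 40.0), spec.get("lat1", 45.0), nrow)
    lons = np.linspace(spec.get("lon0", -70.0), spec.get("lon1", -60.0), ncol)
    depth = np.full((nrow, ncol), float(spec.get("depth", 20.0)))
    for feat in spec.get("features", []):
        r0, r1, c0, c1 = feat["box"]
        if feat["type"] == "land":
            depth[r0:r1, c0:c1] = 0.0
        elif feat["type"] == "set_depth":
            depth[r0:r1, c0:c1] = float(feat["depth"])
        else:
            raise ValueError(f"unknown feature type {feat['type']!r}")
    return BathymetryGrid(lats, lons, depth)


# ---------------------------------------------------------------------------
# Routing
# ---------------------------------------------------------------------------

def _navigable_mask(grid: BathymetryGrid, min_depth: float, max_depth: float) -> np.ndarray:
    return (grid.depth > 0) & (grid.depth >= min_depth) & (grid.depth <= max_depth)


def _build_graph(grid: BathymetryGrid, mask: np.ndarray):
    """Sparse 8-connected adjacency with great-circle weights (km)."""
    nrow, ncol = grid.shape
    idx = np.arange(nrow * ncol).reshape(nrow, ncol)
    rows, cols, data = [], [], []
    lat = grid.lats
    lon = grid.lons
    coslat = np.cos(np.radians(lat))
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        rr = np.arange(nrow - abs(dr))
        cc = np.arange(max(0, -dc), ncol - max(0, dc))
        src = idx[np.ix_(rr, cc)]
        dst = idx[np.ix_(rr + abs(dr), cc + dc)]
        ok = mask[np.ix_(rr, cc)] & mask[np.ix_(rr + abs(dr), cc + dc)]
        # per-row edge lengths
        if dr == 0:
            dlon = (lon[cc + dc] - lon[cc])[None, :]
            seg = np.abs(dlon) * np.pi / 180 * EARTH_RADIUS_KM * coslat[rr][:, None]
        else:
            la1 = lat[rr][:, None]
            la2 = lat[rr + abs(dr)][:, None]
            dlat = np.abs(la2 - la1) * np.pi / 180 * EARTH_RADIUS_KM
            if dc == 0:
                seg = np.broadcast_to(dlat, src.shape).copy()
            else:
                dlon = np.abs(lon[cc + dc] - lon[cc])[None, :] * np.pi / 180 * EARTH_RADIUS_KM
                mid = np.cos(np.radians((la1 + la2) / 2))
                seg = np.sqrt(dlat**2 + (dlon * mid) ** 2)
        rows.append(src[ok])
        cols.append(dst[ok])
        data.append(seg[ok])
    n = nrow * ncol
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    g = coo_matrix((np.concatenate([data, data]),
                    (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
                   shape=(n, n))
    return g.tocsr()


def _snap(grid: BathymetryGrid, mask: np.ndarray, lat: float, lon: float,
          radius: int = 3) -> int:
    """Nearest navigable cell (flat index) within ``radius`` cells."""
    i = int(np.argmin(np.abs(grid.lats - lat)))
    j = int(np.argmin(np.abs(grid.lons - lon)))
    nrow, ncol = grid.shape
    best, best_d = None, np.inf
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            r, c = i + di, j + dj
            if 0 <= r < nrow and 0 <= c < ncol and mask[r, c]:
                d = haversine_km(lat, lon, grid.lats[r], grid.lons[c])
                if d < best_d:
                    best, best_d = r * ncol + c, d
    if best is None:
        raise UnreachableError(
            f"no navigable cell within {radius} cells of ({lat:.3f}, {lon:.3f})"
        )
    return best


def least_cost_distance(grid: BathymetryGrid, origin: tuple[float, float],
                        destination: tuple[float, float], policy: DepthPolicy,
                        site_code: str | None = None, snap_radius: int = 3) -> float:
    """Shortest navigable path length (km) between two lat/lon points.

    ``site_code`` selects the destination site's depth override, which
    applies to the whole path.
    """
    max_depth = policy.max_for(site_code)
    mask = _navigable_mask(grid, policy.min_depth, max_depth)
    src = _snap(grid, mask, *origin, radius=snap_radius)
    dst = _snap(grid, mask, *destination, radius=snap_radius)
    if src == dst:
        return 0.0
    graph = _build_graph(grid, mask)
    dist = dijkstra(graph, indices=src, min_only=False)
    d = dist[dst]
    if not np.isfinite(d):
        raise UnreachableError(
            f"no navigable path at max depth {max_depth} m between "
            f"{origin} and {destination}"
        )
    return float(d)


def transect_distances(grid: BathymetryGrid, sites: pd.DataFrame,
                       policy: DepthPolicy, origin_code: str,
                       snap_radius: int = 3) -> pd.DataFrame:
    """Least-cost km from the origin site to every site.

    Sites sharing the global depth band are routed in one Dijkstra pass;
    sites with overrides are re-routed on their relaxed grid. Unreachable
    sites are reported collectively.
    """
    if origin_code not in set(sites["code"]):
        raise ValueError(f"origin {origin_code!r} not among sites")
    orig = sites.loc[sites["code"] == origin_code].iloc[0]
    out = {}
    failures = []
    # group sites by their effective max depth to share graph builds
    eff = {row["code"]: policy.max_for(row["code"]) for _, row in sites.iterrows()}
    for max_depth in sorted(set(eff.values())):
        mask = _navigable_mask(grid, policy.min_depth, max_depth)
        try:
            src = _snap(grid, mask, orig["lat"], orig["lon"], radius=snap_radius)
        except UnreachableError as exc:
            failures.extend((c, str(exc)) for c, m in eff.items() if m == max_depth)
            continue
        graph = _build_graph(grid, mask)
        dist = dijkstra(graph, indices=src)
        ncol = grid.shape[1]
        for _, row in sites.iterrows():
            if eff[row["code"]] != max_depth:
                continue
            try:
                cell = _snap(grid, mask, row["lat"], row["lon"], radius=snap_radius)
            except UnreachableError as exc:
                failures.append((row["code"], str(exc)))
                continue
            d = dist[cell]
            if not np.isfinite(d):
                failures.append((row["code"], f"unreachable at max depth {max_depth} m"))
            else:
                out[row["code"]] = float(d)
    if failures:
        detail = "; ".join(f"{c}: {msg}" for c, msg in failures)
        raise UnreachableError(f"unreachable sites: {detail}")
    df = sites[["code"]].copy()
    df["distance_km"] = [out[c] for c in df["code"]]
    return df
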