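"""Geodesic hexagonal grids on the sphere.

The grid is the spherical Voronoi diagram of the vertices of a class-I
(frequency-f) subdivided icosahedron — the classical Goldberg-polyhedron
construction.  It tiles the sphere with 10·f² + 2 cells: 12 pentagons at the
icosahedron vertices and hexagons everywhere else.  Cell "diameter" is the
maximum vertex-to-vertex great-circle distance of a cell, and grid resolution
is specified by the target *median* diameter over all cells (e.g. 500 km or
300 km).

Planar coordinates for spatial smooths use the Equal Earth projection with
the 150°E central meridian (EPSG:8859), implemented from the published
projection series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import SphericalVoronoi, cKDTree

EARTH_RADIUS_KM = 6371.0088

# Equal Earth polynomial coefficients (Šavrič, Patterson & Jenny 2019)
_A1, _A2, _A3, _A4 = 1.340264, -0.081106, 0.000893, 0.003796
_M = np.sqrt(3.0) / 2.0
# EPSG:8859 is the Asia-Pacific variant: central meridian 150°E
EQUAL_EARTH_LON0 = 150.0


# ---------------------------------------------------------------------------
# coordinate helpers
# ---------------------------------------------------------------------------

def lonlat_to_unit(lon, lat):
    """Decimal degrees -> unit vectors, shape (..., 3)."""
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    return np.stack([np.cos(phi) * np.cos(lam),
                     np.cos(phi) * np.sin(lam),
                     np.sin(phi)], axis=-1)


def unit_to_lonlat(xyz):
    xyz = np.asarray(xyz, dtype=float)
    lon = np.degrees(np.arctan2(xyz[..., 1], xyz[..., 0]))
    lat = np.degrees(np.arcsin(np.clip(xyz[..., 2], -1.0, 1.0)))
    return lon, lat


def great_circle_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km (haversine)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2, dtype=float)) - np.radians(
        np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(
        dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def validate_lonlat(lon, lat):
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    bad = ~(np.isfinite(lon) & np.isfinite(lat)
            & (lon >= -180.0) & (lon <= 180.0)
            & (lat >= -90.0) & (lat <= 90.0))
    if bad.any():
        rows = np.nonzero(bad)[0]
        raise ValueError(f"invalid coordinates at rows {rows.tolist()[:10]}")
    return lon, lat


# ---------------------------------------------------------------------------
# Equal Earth projection (EPSG:8859)
# ---------------------------------------------------------------------------

def project_equal_earth(lon, lat, lon0=EQUAL_EARTH_LON0,
                        radius_km=EARTH_RADIUS_KM):
    """Forward Equal Earth projection; returns (x, y) in km."""
    lon, lat = validate_lonlat(lon, lat)
    lam = np.radians((lon - lon0 + 180.0) % 360.0 - 180.0)
    phi = np.radians(lat)
    theta = np.arcsin(_M * np.sin(phi))
    t2 = theta * theta
    t6 = t2 * t2 * t2
    denom = _A1 + 3.0 * _A2 * t2 + t6 * (7.0 * _A3 + 9.0 * _A4 * t2)
    x = radius_km * (2.0 * np.sqrt(3.0) / 3.0) * lam * np.cos(theta) / denom
    y = radius_km * theta * (_A1 + _A2 * t2 + t6 * (_A3 + _A4 * t2))
    return x, y


def inverse_equal_earth(x, y, lon0=EQUAL_EARTH_LON0,
                        radius_km=EARTH_RADIUS_KM):
    """Inverse Equal Earth projection via Newton iteration on the parametric
    latitude."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    yr = y / radius_km
    theta = yr.copy()
    for _ in range(12):
        t2 = theta * theta
        t6 = t2 * t2 * t2
        f = theta * (_A1 + _A2 * t2 + t6 * (_A3 + _A4 * t2)) - yr
        fp = _A1 + 3.0 * _A2 * t2 + t6 * (7.0 * _A3 + 9.0 * _A4 * t2)
        theta = theta - f / fp
    t2 = theta * theta
    t6 = t2 * t2 * t2
    denom = _A1 + 3.0 * _A2 * t2 + t6 * (7.0 * _A3 + 9.0 * _A4 * t2)
    lam = x * denom / (radius_km * (2.0 * np.sqrt(3.0) / 3.0)
                       * np.cos(theta))
    phi = np.arcsin(np.clip(np.sin(theta) / _M, -1.0, 1.0))
    lon = (np.degrees(lam) + lon0 + 180.0) % 360.0 - 180.0
    return lon, np.degrees(phi)


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Resolution request: target median cell diameter in km, optionally a
    fixed subdivision frequency (chosen automatically when omitted)."""

    target_median_diameter_km: float = 500.0
    subdivision_frequency: int | None = None

    def __post_init__(self):
        if not (100.0 <= self.target_median_diameter_km <= 2000.0):
            raise ValueError(
                "target median diameter must lie in [100, 2000] km")
        if (self.subdivision_frequency is not None
                and self.subdivision_frequency < 1):
            raise ValueError("subdivision frequency must be >= 1")


@dataclass(frozen=True)
class Cell:
    cell_id: str
    centroid_lon: float
    centroid_lat: float
    centroid_xy: tuple
    boundary: np.ndarray  # (k, 2) lon/lat vertices, k in {5, 6}
    area_km2: float
    diameter_km: float


def _icosahedron_vertices():
    t = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array([[-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
                  [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
                  [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1]],
                 dtype=float)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


_ICO_FACES = np.array([
    [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
    [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
    [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
    [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]])


def icosphere_points(frequency: int) -> np.ndarray:
    """Vertices of the class-I geodesic subdivision; 10·f² + 2 unit vectors."""
    verts = _icosahedron_vertices()
    pts = [verts]
    f = frequency
    for face in _ICO_FACES:
        v0, v1, v2 = verts[face]
        for i in range(f + 1):
            for j in range(f + 1 - i):
                k = f - i - j
                if (i == f) or (j == f) or (k == f):
                    continue  # icosahedron vertices already included
                p = (i * v0 + j * v1 + k * v2) / f
                pts.append(p[None, :])
    pts = np.vstack(pts)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    # dedupe shared edge points
    key = np.round(pts * 1e7).astype(np.int64)
    _, idx = np.unique(key, axis=0, return_index=True)
    out = pts[np.sort(idx)]
    expected = 10 * frequency * frequency + 2
    if len(out) != expected:
        raise RuntimeError(
            f"subdivision produced {len(out)} points, expected {expected}")
    return out


def frequency_for_diameter(target_km: float) -> int:
    """Subdivision frequency whose approximate median hexagon diameter is
    closest to the target (regular-hexagon area heuristic)."""
    def approx_diameter(f):
        n = 10 * f * f + 2
        area = 4.0 * np.pi * EARTH_RADIUS_KM ** 2 / n
        return np.sqrt(8.0 * area / (3.0 * np.sqrt(3.0)))

    f_est = np.sqrt((32.0 * np.pi * EARTH_RADIUS_KM ** 2
                     / (3.0 * np.sqrt(3.0) * target_km ** 2) - 2.0) / 10.0)
    candidates = {max(1, int(np.floor(f_est))), int(np.ceil(f_est)),
                  max(1, int(np.round(f_est)))}
    return min(candidates, key=lambda f: abs(approx_diameter(f) - target_km))


class Grid:
    """Spherical Voronoi tessellation of an icosphere point set.

    Cells carry stable IDs, spherical centroids, Equal Earth projected
    centroids, polygon boundaries, exact spherical areas and diameters.
    Point-to-cell assignment is nearest-centroid on the sphere, which for a
    Voronoi tessellation is exact containment.
    """

    def __init__(self, spec: GridSpec):
        self.spec = spec
        freq = spec.subdivision_frequency
        if freq is None:
            freq = frequency_for_diameter(spec.target_median_diameter_km)
        self.frequency = freq
        points = icosphere_points(freq)
        # stable ordering: north-to-south, then west-to-east
        lon, lat = unit_to_lonlat(points)
        order = np.lexsort((np.round(lon, 9), -np.round(lat, 9)))
        points = points[order]
        self._points = points

        sv = SphericalVoronoi(points, radius=1.0, threshold=1e-9)
        sv.sort_vertices_of_regions()
        areas = sv.calculate_areas() * EARTH_RADIUS_KM ** 2

        lon, lat = unit_to_lonlat(points)
        px, py = project_equal_earth(lon, lat)
        n_digits = max(4, len(str(len(points))))
        cells = []
        diameters = np.empty(len(points))
        for i in range(len(points)):
            vidx = sv.regions[i]
            verts = sv.vertices[vidx]
            blon, blat = unit_to_lonlat(verts)
            # max pairwise chord -> great-circle distance
            d2 = ((verts[:, None, :] - verts[None, :, :]) ** 2).sum(-1)
            chord = np.sqrt(d2.max())
            diam = 2.0 * EARTH_RADIUS_KM * np.arcsin(
                np.clip(chord / 2.0, 0.0, 1.0))
            diameters[i] = diam
            cells.append(Cell(
                cell_id=f"c{i:0{n_digits}d}",
                centroid_lon=float(lon[i]), centroid_lat=float(lat[i]),
                centroid_xy=(float(px[i]), float(py[i])),
                boundary=np.column_stack([blon, blat]),
                area_km2=float(areas[i]), diameter_km=float(diam)))
        self.cells = cells
        self._diameters = diameters
        self._tree = cKDTree(points)
        self._ids = np.array([c.cell_id for c in cells])

        target = spec.target_median_diameter_km
        realized = self.median_diameter_km
        if abs(realized - target) > 0.10 * target:
            raise ValueError(
                f"target median diameter {target} km unattainable; closest "
                f"attainable with frequency {freq} is {realized:.1f} km")

    # ------------------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def median_diameter_km(self) -> float:
        return float(np.median(self._diameters))

    def assign_points(self, lon, lat) -> np.ndarray:
        """Map each (lon, lat) point to the ID of its containing cell."""
        lon, lat = validate_lonlat(lon, lat)
        xyz = lonlat_to_unit(lon, lat)
        _, idx = self._tree.query(np.atleast_2d(xyz))
        ids = self._ids[idx]
        return ids if np.ndim(lon) else ids[0]

    def cell_index(self, cell_ids) -> np.ndarray:
        """Integer positions of cell IDs within this grid."""
        lookup = {cid: i for i, cid in enumerate(self._ids)}
        return np.array([lookup[c] for c in np.atleast_1d(cell_ids)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": [c.cell_id for c in self.cells],
            "centroid_lon": [c.centroid_lon for c in self.cells],
            "centroid_lat": [c.centroid_lat for c in self.cells],
            "centroid_x": [c.centroid_xy[0] for c in self.cells],
            "centroid_y": [c.centroid_xy[1] for c in self.cells],
            "area_km2": [c.area_km2 for c in self.cells],
            "diameter_km": [c.diameter_km for c in self.cells],
        })

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


class GridIndex:
    """Assignment-only lookup built from exported centroids (CSV round-trip)."""

    def __init__(self, cell_ids, lon, lat):
        self._ids = np.asarray(cell_ids)
        self._tree = cKDTree(lonlat_to_unit(lon, lat))

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        return cls(df["cell_id"].to_numpy(), df["centroid_lon"].to_numpy(),
                   df["centroid_lat"].to_numpy())

    def assign_points(self, lon, lat):
        lon, lat = validate_lonlat(lon, lat)
        _, idx = self._tree.query(np.atleast_2d(lonlat_to_unit(lon, lat)))
        ids = self._ids[idx]
        return ids if np.ndim(lon) else ids[0]


def build_grid(spec: GridSpec) -> Grid:
    """Build the geodesic hexagonal grid for a resolution spec."""
    return Grid(spec)


# ---------------------------------------------------------------------------
# jitter
# ---------------------------------------------------------------------------

def jitter_points(lon, lat, max_radius_km, seed=0):
    """Displace points uniformly over the spherical disk of the given radius.

    Angular distance is drawn with CDF proportional to cap area (area-uniform)
    and bearing uniformly; reproducible for a fixed seed.
    """
    if max_radius_km < 0:
        raise ValueError("jitter radius must be non-negative")
    lon, lat = validate_lonlat(lon, lat)
    lon = np.atleast_1d(lon).astype(float)
    lat = np.atleast_1d(lat).astype(float)
    if max_radius_km == 0:
        return lon.copy(), lat.copy()
    rng = np.random.default_rng(seed)
    psi_max = max_radius_km / EARTH_RADIUS_KM
    u = rng.random(lon.shape)
    psi = np.arccos(1.0 - u * (1.0 - np.cos(psi_max)))
    bearing = rng.random(lon.shape) * 2.0 * np.pi
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    sin_phi2 = (np.sin(phi1) * np.cos(psi)
                + np.cos(phi1) * np.sin(psi) * np.cos(bearing))
    phi2 = np.arcsin(np.clip(sin_phi2, -1.0, 1.0))
    lam2 = lam1 + np.arctan2(np.sin(bearing) * np.sin(psi) * np.cos(phi1),
                             np.cos(psi) - np.sin(phi1) * sin_phi2)
    lon2 = (np.degrees(lam2) + 180.0) % 360.0 - 180.0
    return lon2, np.degrees(phi2)
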