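"""Equal-area spherical grids, great-circle geometry and minimum spanning trees.

Fossil localities are discretized onto approximately equal-area grids whose
cells are identified by their centre coordinates.  All distances are
great-circle (haversine) distances on a sphere of radius 6371.0088 km; at the
precision of reconstructed palaeocoordinates an ellipsoid would be spurious
accuracy.

The grid is a latitude-ring construction: the sphere is sliced into rings of
constant height equal to the requested spacing, and each ring is divided into
an integer number of cells chosen so that every cell's area is as close as
possible to ``spacing_km**2``.  The result is a partition of the sphere whose
cell areas stay within a few percent of the mean and whose centre-to-centre
neighbour distances track the nominal spacing — the two properties the
downstream occupancy statistics actually rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088
EARTH_AREA_KM2 = 4.0 * np.pi * EARTH_RADIUS_KM**2


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in km. Accepts scalars or arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards rounding for antipodal points
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def pairwise_great_circle_km(lons, lats):
    """Dense symmetric matrix of great-circle distances between points."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    D = great_circle_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    D = np.asarray(D, dtype=float)
    np.fill_diagonal(D, 0.0)
    return D


class EqualAreaGrid:
    """Quasi-equal-area latitude-ring grid with integer cell ids.

    Parameters
    ----------
    spacing_km : float
        Nominal centre-to-centre distance between neighbouring cells.
        Typical analysis spacings are 100, 200, 500, 1000 and 5000 km.
    """

    def __init__(self, spacing_km: float):
        if not np.isfinite(spacing_km) or spacing_km <= 0:
            raise ValueError(f"spacing_km must be positive, got {spacing_km!r}")
        self.spacing_km = float(spacing_km)
        n_rings = max(1, int(round(np.pi * EARTH_RADIUS_KM / spacing_km)))
        self.n_rings = n_rings
        # ring boundaries in colatitude
        edges = np.linspace(0.0, np.pi, n_rings + 1)
        self._ring_edges = edges
        cos_edges = np.cos(edges)
        ring_areas = 2.0 * np.pi * EARTH_RADIUS_KM**2 * (cos_edges[:-1] - cos_edges[1:])
        target_cell_area = spacing_km**2
        self._cells_per_ring = np.maximum(1, np.round(ring_areas / target_cell_area)).astype(int)
        self._ring_offsets = np.concatenate([[0], np.cumsum(self._cells_per_ring)])
        self.n_cells = int(self._ring_offsets[-1])
        self._ring_areas = ring_areas

    def assign_cell(self, lon, lat):
        """Map lon/lat degrees to integer cell ids (vectorized)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(np.abs(lat) > 90.0 + 1e-9) or np.any(np.abs(lon) > 180.0 + 1e-9):
            raise ValueError("coordinates out of bounds")
        colat = np.radians(90.0 - lat)
        ring = np.clip(
            (colat / np.pi * self.n_rings).astype(int), 0, self.n_rings - 1
        )
        ncells = self._cells_per_ring[ring]
        frac = (np.mod(lon + 180.0, 360.0)) / 360.0
        idx = np.minimum((frac * ncells).astype(int), ncells - 1)
        cell = self._ring_offsets[ring] + idx
        if cell.ndim == 0:
            return int(cell)
        return cell

    def cell_center(self, cell_id):
        """Centre lon/lat degrees of cells (vectorized)."""
        cell_id = np.asarray(cell_id)
        ring = np.searchsorted(self._ring_offsets, cell_id, side="right") - 1
        idx = cell_id - self._ring_offsets[ring]
        ncells = self._cells_per_ring[ring]
        colat = 0.5 * (self._ring_edges[ring] + self._ring_edges[ring + 1])
        lat = 90.0 - np.degrees(colat)
        lon = (idx + 0.5) / ncells * 360.0 - 180.0
        if cell_id.ndim == 0:
            return float(lon), float(lat)
        return lon, lat

    def cell_areas_km2(self):
        """Exact area of every cell (cells within a ring share one area)."""
        per_ring = self._ring_areas / self._cells_per_ring
        return np.repeat(per_ring, self._cells_per_ring)


def build_grid(spacing_km: float) -> EqualAreaGrid:
    return EqualAreaGrid(spacing_km)


@dataclass(frozen=True)
class MSTResult:
    """Minimum spanning tree over a point set on the sphere.

    ``edges`` holds (index_a, index_b, length_km) triples referring to the
    positional indices of the input points.  A single point yields an empty
    tree with zero total length.
    """

    total_length_km: float
    longest_branch_km: float
    edges: tuple


def minimum_spanning_tree_from_matrix(D) -> MSTResult:
    """Prim's algorithm on a dense symmetric distance matrix.

    Written out rather than delegated so that exact-zero edges between
    coincident points are retained (sparse-graph MSTs treat 0 as "no edge").
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n == 0:
        raise ValueError("MST of an empty point set is undefined")
    if n == 1:
        return MSTResult(0.0, 0.0, ())
    best = D[0].copy()
    parent = np.zeros(n, dtype=int)
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best[0] = np.inf
    edges = []
    for _ in range(n - 1):
        j = int(np.argmin(best))
        edges.append((int(parent[j]), j, float(best[j])))
        in_tree[j] = True
        best[j] = np.inf
        closer = D[j] < best
        closer &= ~in_tree
        parent[closer] = j
        best[closer] = D[j][closer]
    lengths = [e[2] for e in edges]
    return MSTResult(float(sum(lengths)), float(max(lengths)), tuple(edges))


def minimum_spanning_tree(lons, lats) -> MSTResult:
    """MST over points given as lon/lat degree arrays (great-circle weights)."""
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if lons.size == 0:
        raise ValueError("MST of an empty point set is undefined")
    return minimum_spanning_tree_from_matrix(pairwise_great_circle_km(lons, lats))


def count_occupied_cells(lons, lats, spacing_km, grid: EqualAreaGrid | None = None) -> int:
    """Number of distinct grid cells at ``spacing_km`` holding >=1 point."""
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    if lons.size == 0:
        return 0
    g = grid if grid is not None else EqualAreaGrid(spacing_km)
    cells = g.assign_cell(lons, np.atleast_1d(np.asarray(lats, dtype=float)))
    return int(np.unique(np.atleast_1d(cells)).size)


LATITUDE_ZONES = (("low", 0.0, 30.0), ("mid", 30.0, 60.0), ("high", 60.0, 90.0))


def _zone_of(abs_lat):
    # half-open [0,30), [30,60), closed top [60,90]
    if abs_lat < 30.0:
        return "low"
    if abs_lat < 60.0:
        return "mid"
    return "high"


def spatial_sampling_summary(occurrences, spacing_km, grid: EqualAreaGrid | None = None):
    """Per-bin occupied-cell counts split by hemisphere, |latitude| zone and region code.

    ``occurrences`` is a DataFrame with ``bin_id``, ``paleo_lon``, ``paleo_lat``
    and (for the continental split) ``region_code`` columns.  Zone membership is
    decided by the cell *centre* latitude; the continental stratum of a cell is
    the modal region code of the records it contains.  Returns a tidy frame
    (bin_id, stratum_type, stratum, count).
    """
    import pandas as pd

    g = grid if grid is not None else EqualAreaGrid(spacing_km)
    df = occurrences.copy()
    df["_cell"] = g.assign_cell(df["paleo_lon"].to_numpy(), df["paleo_lat"].to_numpy())
    rows = []
    for bin_id, sub in df.groupby("bin_id", sort=True):
        cells = np.unique(sub["_cell"].to_numpy())
        _, centre_lat = g.cell_center(cells)
        centre_lat = np.atleast_1d(centre_lat)
        hemi = np.where(centre_lat >= 0.0, "N", "S")
        for h in ("N", "S"):
            rows.append((bin_id, "hemisphere", h, int(np.sum(hemi == h))))
        zones = [_zone_of(abs(la)) for la in centre_lat]
        for z, _, _ in LATITUDE_ZONES:
            rows.append((bin_id, "latitude_zone", z, zones.count(z)))
        if "region_code" in sub.columns:
            modal = sub.groupby("_cell")["region_code"].agg(
                lambda s: s.mode().iloc[0] if len(s.mode()) else ""
            )
            for code, cnt in modal.value_counts().items():
                rows.append((bin_id, "continent", code, int(cnt)))
    return pd.DataFrame(rows, columns=["bin_id", "stratum_type", "stratum", "count"])
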