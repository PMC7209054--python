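"""Enumeration and characterization of palaeogeographical regions.

A *spatial point* is a 100-km equal-area grid cell containing at least one
fossil occurrence.  For each time bin, the enumeration grows a region from
every possible starting point by repeatedly absorbing the not-yet-included
point closest to the current member set (single linkage: the candidate's
distance is its minimum great-circle distance to any member, measured between
cell centres), saving every intermediate member set of size >= 2.  Exact
duplicate member sets arising from different starts are discarded.  Ties in
the accretion step are broken uniformly at random with a seeded generator, so
the full procedure is deterministic given its seed.

Characterization attaches spatial metadata (MST, occupied-cell counts at a
range of spacings), sampling metadata (collections, literature references,
coverage statistics) and richness estimates to each enumerated member set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import (
    EqualAreaGrid,
    MSTResult,
    minimum_spanning_tree_from_matrix,
    pairwise_great_circle_km,
)
from . import richness as rich

#: absolute tie tolerance for accretion distances, in km
TIE_TOL_KM = 1e-9


@dataclass(frozen=True)
class RegionSkeleton:
    """Member set of a region, in accretion order."""

    bin_id: str
    member_ids: tuple


@dataclass
class Region:
    bin_id: str
    member_ids: tuple
    mst: MSTResult
    occupied_cells: dict
    n_occurrences: int
    n_collections: int
    n_references: int
    coverage: rich.CoverageStats | None
    richness: dict
    dominant_region_code: str
    region_codes: frozenset

    @property
    def longest_branch_frac(self) -> float:
        if self.mst.total_length_km == 0:
            return 0.0
        return self.mst.longest_branch_km / self.mst.total_length_km


def enumerate_regions(cell_ids, lons, lats, seed: int = 0, bin_id: str = ""):
    """All nested sets of adjacent spatial points, one growth chain per start.

    Returns a list of :class:`RegionSkeleton` (deduplicated by member set,
    keeping the first accretion order encountered).  Starts are visited in
    ascending cell-id order so the output is deterministic given ``seed``.
    """
    cell_ids = np.asarray(cell_ids)
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    P = len(cell_ids)
    if P < 2:
        warnings.warn("need at least two spatial points to enumerate regions", stacklevel=2)
        return []
    D = pairwise_great_circle_km(lons, lats)
    rng = np.random.default_rng(seed)
    seen = set()
    out = []
    for s in np.argsort(cell_ids, kind="stable"):
        mind = D[s].copy()
        in_set = np.zeros(P, dtype=bool)
        in_set[s] = True
        mind[s] = np.inf
        members = [int(s)]
        for _ in range(P - 1):
            mmin = mind.min()
            cand = np.flatnonzero(mind <= mmin + TIE_TOL_KM)
            c = int(cand[0]) if cand.size == 1 else int(rng.choice(cand))
            members.append(c)
            in_set[c] = True
            mind = np.minimum(mind, D[c])
            mind[in_set] = np.inf
            key = frozenset(members)
            if key not in seen:
                seen.add(key)
                out.append(
                    RegionSkeleton(bin_id, tuple(cell_ids[i] for i in members))
                )
    return out


def attach_cells(df: pd.DataFrame, grids: dict) -> pd.DataFrame:
    """Add ``cell_{spacing}`` columns assigning every occurrence to its grid cells."""
    out = df.copy()
    for spacing, grid in grids.items():
        out[f"cell_{spacing:g}"] = grid.assign_cell(
            out["paleo_lon"].to_numpy(), out["paleo_lat"].to_numpy()
        )
    return out


def characterize_region(
    skeleton: RegionSkeleton,
    occurrences: pd.DataFrame,
    grids: dict,
    quorums=(0.4, 0.6, 0.8),
    gcr_configs=(),
    point_spacing: float = 100.0,
    compute_richness: bool = True,
) -> Region:
    """Fill all metadata for one region.

    ``occurrences`` must be the bin's occurrence frame already passed through
    :func:`attach_cells` for all ``grids`` (which must include the
    ``point_spacing`` grid defining the spatial points).  Estimator failures
    become missing values, never exceptions.
    """
    grid0 = grids[point_spacing]
    member = np.asarray(skeleton.member_ids)
    occ = occurrences[occurrences[f"cell_{point_spacing:g}"].isin(member)]

    lon_c, lat_c = grid0.cell_center(member)
    mst = minimum_spanning_tree_from_matrix(
        pairwise_great_circle_km(np.atleast_1d(lon_c), np.atleast_1d(lat_c))
    )

    occupied = {}
    for spacing in grids:
        occupied[spacing] = int(occ[f"cell_{spacing:g}"].nunique())

    n_occ = int(len(occ))
    n_coll = int(occ["collection_id"].nunique())
    n_refs = int(occ["reference_id"].nunique())

    colls = occ.drop_duplicates("collection_id")
    codes = colls["region_code"].fillna("").astype(str)
    codes = codes[codes != ""]
    dominant = codes.mode().iloc[0] if len(codes) else ""
    code_set = frozenset(codes.unique())

    coverage = None
    richness_map: dict = {}
    if n_occ > 0:
        counts = rich.frequency_vector(occ["taxon_name"])
        try:
            coverage = rich.coverage_stats(counts)
        except ValueError:
            coverage = None
        if compute_richness:
            richness_map["face_value"] = rich.face_value(counts)
            for q in quorums:
                richness_map[f"sqs_q{q:g}"] = rich.sqs_richness(counts, q)
            inc = occ.groupby("taxon_name")["collection_id"].nunique().to_numpy()
            richness_map["chao2"] = rich.chao2(inc, n_coll)
            richness_map["squares"] = rich.squares(counts)
            for cfg in gcr_configs:
                for q in quorums:
                    key = f"sqs_gcr{cfg.quota_per_1000km}_q{q:g}"
                    richness_map[key] = rich.gcr_sqs(
                        occ[f"cell_{cfg.cell_spacing_km:g}"],
                        occ["taxon_name"],
                        mst.total_length_km,
                        cfg,
                        q,
                    )
    return Region(
        bin_id=skeleton.bin_id,
        member_ids=tuple(skeleton.member_ids),
        mst=mst,
        occupied_cells=occupied,
        n_occurrences=n_occ,
        n_collections=n_coll,
        n_references=n_refs,
        coverage=coverage,
        richness=richness_map,
        dominant_region_code=dominant,
        region_codes=code_set,
    )


def characterize_bin(
    skeletons,
    occurrences: pd.DataFrame,
    grids: dict,
    point_spacing: float = 100.0,
) -> list:
    """Vectorized spatial/sampling metadata for all regions of one bin.

    Produces the same :class:`Region` objects as calling
    :func:`characterize_region` with ``compute_richness=False`` on each
    skeleton (a contract asserted in the test suite), but factorizes the
    occurrence table once and works on integer arrays, which is what makes
    enumerating thousands of nested regions per bin tractable.
    """
    if not skeletons:
        return []
    grid0 = grids[point_spacing]
    cell_col = f"cell_{point_spacing:g}"
    occ = occurrences

    cell_ids = np.array(sorted({m for sk in skeletons for m in sk.member_ids}))
    cell_index = {c: i for i, c in enumerate(cell_ids)}
    lon_c, lat_c = grid0.cell_center(cell_ids)
    D = pairwise_great_circle_km(np.atleast_1d(lon_c), np.atleast_1d(lat_c))

    # factorize once
    occ_cell = occ[cell_col].map(cell_index).to_numpy()
    valid = ~pd.isna(occ_cell)
    occ = occ[valid]
    occ_cell = occ_cell[valid].astype(int)
    ref_codes, _ = pd.factorize(occ["reference_id"])
    sp_codes, _ = pd.factorize(occ["taxon_name"])
    coll_codes, coll_uniques = pd.factorize(occ["collection_id"])
    spacing_codes = {}
    for spacing in grids:
        spacing_codes[spacing] = pd.factorize(occ[f"cell_{spacing:g}"])[0]

    # modal region code per collection
    colls = occ.drop_duplicates("collection_id")
    coll_code_map = dict(
        zip(pd.factorize(colls["collection_id"])[0], colls["region_code"].fillna("").astype(str))
    )
    coll_region = np.array(
        [coll_code_map.get(i, "") for i in range(len(coll_uniques))], dtype=object
    )

    # occurrence rows per cell
    order = np.argsort(occ_cell, kind="stable")
    sorted_cells = occ_cell[order]
    boundaries = np.searchsorted(sorted_cells, np.arange(len(cell_ids) + 1))
    rows_by_cell = [order[boundaries[i] : boundaries[i + 1]] for i in range(len(cell_ids))]

    out = []
    for sk in skeletons:
        idx = np.array([cell_index[m] for m in sk.member_ids])
        mst = minimum_spanning_tree_from_matrix(D[np.ix_(idx, idx)])
        rows = (
            np.concatenate([rows_by_cell[i] for i in idx])
            if len(idx)
            else np.array([], dtype=int)
        )
        n_occ = int(rows.size)
        if n_occ:
            coll_sel = np.unique(coll_codes[rows])
            n_coll = int(coll_sel.size)
            n_refs = int(np.unique(ref_codes[rows]).size)
            occupied = {
                spacing: int(np.unique(spacing_codes[spacing][rows]).size)
                for spacing in grids
            }
            counts = np.bincount(sp_codes[rows])
            counts = counts[counts > 0]
            n = counts.sum()
            s_obs = counts.size
            f1 = int(np.sum(counts == 1))
            f2 = int(np.sum(counts == 2))
            coverage = rich.CoverageStats(
                float(1.0 - f1 / n),
                float((s_obs - f1) / s_obs),
                float(1.0 - (f1 / n) * rich._coverage_A(n, f1, f2)),
            )
            codes = coll_region[coll_sel]
            codes = codes[codes != ""]
            if codes.size:
                vals, cnts = np.unique(codes, return_counts=True)
                dominant = str(min(vals[cnts == cnts.max()]))
                code_set = frozenset(vals.tolist())
            else:
                dominant, code_set = "", frozenset()
        else:
            n_coll = n_refs = 0
            occupied = {spacing: 0 for spacing in grids}
            coverage = None
            dominant, code_set = "", frozenset()
        out.append(
            Region(
                bin_id=sk.bin_id,
                member_ids=tuple(sk.member_ids),
                mst=mst,
                occupied_cells=occupied,
                n_occurrences=n_occ,
                n_collections=n_coll,
                n_references=n_refs,
                coverage=coverage,
                richness={},
                dominant_region_code=dominant,
                region_codes=code_set,
            )
        )
    return out


def regions_to_frame(regions) -> pd.DataFrame:
    """Tidy one-row-per-region metadata table for filtering and clustering."""
    rows = []
    for i, r in enumerate(regions):
        row = {
            "region_index": i,
            "bin_id": r.bin_id,
            "member_ids": tuple(sorted(r.member_ids)),
            "n_points": len(r.member_ids),
            "mst_total_km": r.mst.total_length_km,
            "mst_longest_km": r.mst.longest_branch_km,
            "longest_branch_frac": r.longest_branch_frac,
            "n_occurrences": r.n_occurrences,
            "n_collections": r.n_collections,
            "n_references": r.n_references,
            "goods_u": r.coverage.goods_u if r.coverage else np.nan,
            "multiton_ratio": r.coverage.multiton_ratio if r.coverage else np.nan,
            "chao_jost_coverage": r.coverage.chao_jost_coverage if r.coverage else np.nan,
            "dominant_region_code": r.dominant_region_code,
            "region_codes": r.region_codes,
        }
        for spacing, count in r.occupied_cells.items():
            row[f"occupied_cells_{spacing:g}"] = count
        for key, est in r.richness.items():
            row[f"richness_{key}"] = est.value
        rows.append(row)
    return pd.DataFrame(rows)
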