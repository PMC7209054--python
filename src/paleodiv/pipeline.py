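"""End-to-end orchestration: ingest -> bin -> enumerate -> standardize -> model.

`run_pipeline` executes the full analysis from one config and returns all
intermediate and final tables plus a manifest with per-stage record counts,
so every occurrence is either carried forward or accounted for in a named
drop category.  One master seed deterministically spawns per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grid import EqualAreaGrid, spatial_sampling_summary
from .occurrences import (
    ExclusionConfig,
    assign_time_bins,
    clean_occurrences,
    read_occurrences,
)
from .regions import (
    attach_cells,
    characterize_bin,
    characterize_region,
    enumerate_regions,
    regions_to_frame,
)
from .standardize import (
    DEFAULT_BARRIER_RULES,
    DEFAULT_MST_TARGETS,
    StandardizationCriteria,
    apply_barrier_rules,
    cluster_regions,
    filter_regions,
    summarize_clusters,
)
from .trends import fit_diversity_models, global_timeseries

POINT_SPACING_KM = 100.0


@dataclass
class PipelineConfig:
    bins: list = None  # list of TimeBin; required
    exclusions: ExclusionConfig = field(default_factory=ExclusionConfig)
    spacings: tuple = (100.0, 200.0, 500.0, 1000.0, 5000.0)
    mst_targets: tuple = DEFAULT_MST_TARGETS
    mst_tolerance: float = 0.10
    max_longest_branch_frac: float = 0.40
    min_references: int = 20
    min_multiton_ratio: float = 0.25
    barrier_rules: tuple = DEFAULT_BARRIER_RULES
    quorums: tuple = (0.4, 0.6, 0.8)
    gcr_configs: tuple = ()
    cluster_overlap: float = 0.25
    boundary_ma: float = 66.0
    response: str = "richness_sqs_q0.6"
    seed: int = 0

    def criteria(self, target: float) -> StandardizationCriteria:
        return StandardizationCriteria(
            target_mst_km=target,
            mst_tolerance=self.mst_tolerance,
            max_longest_branch_frac=self.max_longest_branch_frac,
            min_references=self.min_references,
            min_multiton_ratio=self.min_multiton_ratio,
        )


@dataclass
class PipelineResult:
    occurrences: pd.DataFrame
    region_frame: pd.DataFrame
    standardized: dict  # target -> region frame surviving all filters
    cluster_summaries: dict  # target -> tidy summary frame
    diversity_points: dict  # target -> one row per cluster (midpoint, response)
    model_tables: dict  # target -> AICc comparison table
    timeseries: pd.DataFrame
    sampling_summary: pd.DataFrame
    manifest: dict


SUMMARY_VARIABLES = (
    "mst_total_km",
    "n_occurrences",
    "n_collections",
    "n_references",
    "goods_u",
    "multiton_ratio",
)


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(occurrences, cfg: PipelineConfig) -> PipelineResult:
    """Run the full spatial-standardization analysis.

    ``occurrences`` is a path to an occurrence CSV or an already-canonical
    DataFrame.  Raises on hard stage errors; empty surviving-region sets at a
    spatial scale produce empty outputs, not errors.
    """
    if cfg.bins is None:
        raise ValueError("PipelineConfig.bins is required")
    manifest = {"version": __version__, "seed": cfg.seed, "stages": {}}

    # --- ingest ------------------------------------------------------------
    if isinstance(occurrences, (str, Path)):
        df, report = read_occurrences(occurrences)
        manifest["stages"]["ingest"] = report
    else:
        df = occurrences.copy()
        if "taxon_name" not in df.columns:  # PBDB-dialect frame
            from .occurrences import PBDB_DIALECT

            df = df.rename(columns=PBDB_DIALECT)
        manifest["stages"]["ingest"] = {"n_input": int(len(df)), "n_retained": int(len(df))}

    # --- clean -------------------------------------------------------------
    df, tallies = clean_occurrences(df, cfg.exclusions)
    tallies["n_retained"] = int(len(df))
    manifest["stages"]["clean"] = tallies

    # --- bin ---------------------------------------------------------------
    df, dropped = assign_time_bins(df, cfg.bins)
    manifest["stages"]["bin"] = {"dropped_unbinned": dropped, "n_retained": int(len(df))}

    grids = {s: EqualAreaGrid(s) for s in cfg.spacings}
    if POINT_SPACING_KM not in grids:
        grids[POINT_SPACING_KM] = EqualAreaGrid(POINT_SPACING_KM)
    df = attach_cells(df, grids)

    # --- spatial points & region enumeration per bin -----------------------
    grid0 = grids[POINT_SPACING_KM]
    all_regions = []
    enum_seed = _stage_seed(cfg.seed, "enumerate")
    for b in cfg.bins:
        sub = df[df["bin_id"] == b.bin_id]
        if sub.empty:
            continue
        cells = np.sort(sub[f"cell_{POINT_SPACING_KM:g}"].unique())
        lon_c, lat_c = grid0.cell_center(cells)
        if len(cells) < 2:
            continue
        skeletons = enumerate_regions(
            cells, np.atleast_1d(lon_c), np.atleast_1d(lat_c),
            seed=enum_seed, bin_id=b.bin_id,
        )
        # cheap metadata for every region; richness later for survivors only
        all_regions.extend(characterize_bin(skeletons, sub, grids))
    manifest["stages"]["enumerate"] = {
        "n_spatial_points": int(sum(
            df[df["bin_id"] == b.bin_id][f"cell_{POINT_SPACING_KM:g}"].nunique()
            for b in cfg.bins
        )),
        "n_regions": len(all_regions),
    }
    region_frame = regions_to_frame(all_regions)

    # --- standardization per spatial scale ---------------------------------
    midpoints = {b.bin_id: b.midpoint_ma for b in cfg.bins}
    standardized = {}
    survivors_union = set()
    for target in cfg.mst_targets:
        if region_frame.empty:
            standardized[target] = region_frame
            continue
        kept = filter_regions(region_frame, cfg.criteria(target))
        kept = apply_barrier_rules(kept, cfg.barrier_rules, midpoints)
        standardized[target] = kept
        survivors_union.update(kept["region_index"].tolist())

    # --- richness estimates for surviving regions --------------------------
    richness_cols = {}
    by_bin = {b.bin_id: df[df["bin_id"] == b.bin_id] for b in cfg.bins}
    for idx in sorted(survivors_union):
        r = all_regions[idx]
        full = characterize_region(
            _skeleton_of(r), by_bin[r.bin_id], grids, cfg.quorums,
            gcr_configs=cfg.gcr_configs,
        )
        for key, est in full.richness.items():
            richness_cols.setdefault(f"richness_{key}", {})[idx] = est.value
    for col, values in richness_cols.items():
        region_frame[col] = region_frame["region_index"].map(values)
    for target in cfg.mst_targets:
        kept = standardized[target]
        if kept.empty:
            continue
        standardized[target] = region_frame.loc[kept.index]
    manifest["stages"]["standardize"] = {
        f"{target:g}km": int(len(standardized[target])) for target in cfg.mst_targets
    }

    # --- clustering + summaries + model fits -------------------------------
    response_col = cfg.response
    cluster_summaries = {}
    diversity_points = {}
    model_tables = {}
    variables = list(SUMMARY_VARIABLES) + sorted(richness_cols)
    for target in cfg.mst_targets:
        kept = standardized[target]
        summaries = []
        points = []
        for bin_id, sub in kept.groupby("bin_id", sort=True) if len(kept) else []:
            labels = cluster_regions(sub, cfg.cluster_overlap)
            summary = summarize_clusters(sub, labels, [v for v in variables if v in sub])
            summary.insert(0, "target_mst_km", target)
            summaries.append(summary)
            if response_col in sub:
                sub = sub.copy()
                sub["_cluster"] = labels
                for cl, csub in sub.groupby("_cluster"):
                    vals = csub[response_col].dropna()
                    if len(vals):
                        points.append(
                            {"bin_id": bin_id, "midpoint_ma": midpoints[bin_id],
                             "cluster_id": int(cl), "n_regions": int(len(vals)),
                             "median_richness": float(np.median(vals)),
                             "median_log_richness": float(np.log(np.median(vals)))
                             if np.median(vals) > 0 else np.nan}
                        )
        cluster_summaries[target] = (
            pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
        )
        pts = pd.DataFrame(points)
        diversity_points[target] = pts
        if len(pts) and len(pts.dropna(subset=["median_log_richness"])) >= 8:
            model_tables[target] = fit_diversity_models(
                pts, response="median_log_richness", boundary_ma=cfg.boundary_ma
            )
        else:
            model_tables[target] = pd.DataFrame()
    manifest["stages"]["cluster"] = {
        f"{t:g}km": int(diversity_points[t]["cluster_id"].count()) if len(diversity_points[t]) else 0
        for t in cfg.mst_targets
    }

    # --- global time series and sampling summary ----------------------------
    timeseries = global_timeseries(df, cfg.bins, cfg.quorums, cfg.spacings, grids)
    summary_spacing = 1000.0 if 1000.0 in grids else max(grids)
    sampling_summary = spatial_sampling_summary(df, summary_spacing, grids[summary_spacing])
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(_config_fingerprint(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]

    return PipelineResult(
        occurrences=df,
        region_frame=region_frame,
        standardized=standardized,
        cluster_summaries=cluster_summaries,
        diversity_points=diversity_points,
        model_tables=model_tables,
        timeseries=timeseries,
        sampling_summary=sampling_summary,
        manifest=manifest,
    )


def _skeleton_of(region):
    from .regions import RegionSkeleton

    return RegionSkeleton(region.bin_id, region.member_ids)


def _config_fingerprint(cfg: PipelineConfig) -> dict:
    return {
        "bins": [(b.bin_id, b.early_ma, b.late_ma) for b in cfg.bins],
        "spacings": list(cfg.spacings),
        "mst_targets": list(cfg.mst_targets),
        "mst_tolerance": cfg.mst_tolerance,
        "max_longest_branch_frac": cfg.max_longest_branch_frac,
        "min_references": cfg.min_references,
        "min_multiton_ratio": cfg.min_multiton_ratio,
        "quorums": list(cfg.quorums),
        "cluster_overlap": cfg.cluster_overlap,
        "boundary_ma": cfg.boundary_ma,
        "response": cfg.response,
        "seed": cfg.seed,
    }


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write all result tables as tidy CSV plus the JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.timeseries.to_csv(out / "global_timeseries.csv", index=False)
    result.sampling_summary.to_csv(out / "spatial_sampling_summary.csv", index=False)
    occ = result.occurrences.drop(columns=[c for c in result.occurrences.columns
                                           if c.startswith("cell_")])
    occ.to_csv(out / "occurrences_cleaned_binned.csv", index=False)
    with open(out / "cleaning_report.json", "w") as fh:
        json.dump(result.manifest["stages"], fh, indent=2)
    rf = result.region_frame.copy()
    if len(rf):
        rf["member_ids"] = rf["member_ids"].map(lambda t: ";".join(map(str, t)))
        rf["region_codes"] = rf["region_codes"].map(lambda s: ";".join(sorted(s)))
    rf.to_csv(out / "regions.csv", index=False)
    for target, summary in result.cluster_summaries.items():
        summary.to_csv(out / f"cluster_summary_{target:g}km.csv", index=False)
    for target, table in result.model_tables.items():
        if len(table):
            table.drop(columns=["coefficients"]).to_csv(
                out / f"model_comparison_{target:g}km.csv", index=False
            )
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
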