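"""Spatial standardization: filtering, barrier rules, clustering, summaries.

Regions are standardized by keeping only those that simultaneously satisfy a
target MST length (within a relative tolerance), a cap on the longest MST
branch as a fraction of the total (excluding widely separated locality
clusters), a minimum number of literature references (a research-effort
floor), and a minimum multiton ratio (a sample-completeness floor).  Regions
spanning geographically implausible combinations of land masses at a given
time (e.g. South America + Africa after the Atlantic opened) are removed by
barrier rules.  Because the enumeration saves every nested member set, the
survivors are grouped into clusters of mutually overlapping regions and each
cluster is summarized by per-variable medians and interquartile ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

#: spatial scales (target MST lengths, km) iterated by the pipeline driver
DEFAULT_MST_TARGETS = (1000.0, 1500.0, 2000.0, 2500.0, 3000.0, 3500.0, 4000.0)


@dataclass(frozen=True)
class StandardizationCriteria:
    target_mst_km: float = 2000.0
    mst_tolerance: float = 0.10
    max_longest_branch_frac: float = 0.40
    min_references: int = 20
    min_multiton_ratio: float = 0.25


@dataclass(frozen=True)
class BarrierRule:
    """Region-code sets that cannot co-occur in one region after a given time."""

    side_a: frozenset
    side_b: frozenset
    active_after_ma: float

    def __post_init__(self):
        if not self.side_a or not self.side_b or (self.side_a & self.side_b):
            raise ValueError("barrier sides must be disjoint and nonempty")


DEFAULT_BARRIER_RULES = (
    BarrierRule(frozenset({"SA"}), frozenset({"AF"}), 120.0),
    BarrierRule(frozenset({"AUS"}), frozenset({"NZ"}), 70.0),
    BarrierRule(frozenset({"EU"}), frozenset({"AF"}), 66.0),
)


def filter_regions(frame: pd.DataFrame, criteria: StandardizationCriteria) -> pd.DataFrame:
    """Keep regions satisfying all four standardization criteria (conjunctive)."""
    lo = criteria.target_mst_km * (1.0 - criteria.mst_tolerance)
    hi = criteria.target_mst_km * (1.0 + criteria.mst_tolerance)
    keep = (
        (frame["mst_total_km"] >= lo)
        & (frame["mst_total_km"] <= hi)
        & (frame["longest_branch_frac"] <= criteria.max_longest_branch_frac)
        & (frame["n_references"] >= criteria.min_references)
        & (frame["multiton_ratio"] >= criteria.min_multiton_ratio)
    )
    return frame[keep]


def apply_barrier_rules(frame: pd.DataFrame, rules, bin_midpoints: dict) -> pd.DataFrame:
    """Remove regions straddling an active barrier.

    A rule is active for a region when the region's bin midpoint is younger
    than ``active_after_ma``; the region is removed if its member collections
    carry codes from both sides.  ``bin_midpoints`` maps bin_id -> Ma.
    """
    if not len(frame):
        return frame
    known = set()
    for r in rules:
        known |= r.side_a | r.side_b

    def crosses(row):
        mid = bin_midpoints.get(row["bin_id"])
        if mid is None:
            return False
        codes = set(row["region_codes"])
        for rule in rules:
            if mid < rule.active_after_ma and (codes & rule.side_a) and (codes & rule.side_b):
                return True
        return False

    mask = frame.apply(crosses, axis=1)
    return frame[~mask]


def _overlap_components(member_sets, threshold):
    """Connected components of the pairwise-overlap graph.

    overlap(A, B) = |A ∩ B| / min(|A|, |B|); an edge exists when overlap
    strictly exceeds ``threshold``.  Single-linkage transitive closure is
    exactly the connected-component structure, so the partition is invariant
    to input order.
    """
    n = len(member_sets)
    universe = sorted({p for s in member_sets for p in s})
    index = {p: i for i, p in enumerate(universe)}
    rows, cols = [], []
    for i, s in enumerate(member_sets):
        for p in s:
            rows.append(i)
            cols.append(index[p])
    M = csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(n, len(universe)),
    )
    inter = (M @ M.T).toarray()
    sizes = np.array([len(s) for s in member_sets])
    min_size = np.minimum(sizes[:, None], sizes[None, :])
    with np.errstate(invalid="ignore"):
        overlap = inter / min_size
    adj = overlap > threshold
    np.fill_diagonal(adj, True)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def cluster_regions(frame: pd.DataFrame, overlap_threshold: float = 0.25) -> np.ndarray:
    """Cluster overlapping regions; returns an integer label per frame row.

    Labels are canonicalized by the processing order regions sorted by
    descending member count, ties by lexicographic member ids, so the result
    is identical under any shuffling of the input rows.
    """
    if not len(frame):
        return np.array([], dtype=int)
    member_sets = [frozenset(m) for m in frame["member_ids"]]
    raw = _overlap_components(member_sets, overlap_threshold)
    order = sorted(
        range(len(member_sets)),
        key=lambda i: (-len(member_sets[i]), tuple(sorted(member_sets[i]))),
    )
    relabel = {}
    for i in order:
        if raw[i] not in relabel:
            relabel[raw[i]] = len(relabel)
    return np.array([relabel[r] for r in raw], dtype=int)


def summarize_clusters(frame: pd.DataFrame, labels, variables) -> pd.DataFrame:
    """Median and IQR per cluster and variable, ignoring missing values.

    Quartiles use linear interpolation between order statistics.  Returns a
    tidy frame (bin_id, cluster_id, variable, median, iqr, n_regions,
    dominant_region_code).
    """
    frame = frame.copy()
    frame["_cluster"] = np.asarray(labels)
    rows = []
    for cluster_id, sub in frame.groupby("_cluster", sort=True):
        bin_id = sub["bin_id"].iloc[0] if "bin_id" in sub else ""
        codes = sub.get("dominant_region_code")
        dominant = ""
        if codes is not None:
            nonempty = codes[codes != ""]
            if len(nonempty):
                dominant = nonempty.mode().iloc[0]
        for var in variables:
            vals = pd.to_numeric(sub[var], errors="coerce").dropna().to_numpy()
            if vals.size:
                med = float(np.median(vals))
                iqr = float(np.percentile(vals, 75) - np.percentile(vals, 25))
            else:
                med, iqr = np.nan, np.nan
            rows.append(
                {
                    "bin_id": bin_id,
                    "cluster_id": int(cluster_id),
                    "variable": var,
                    "median": med,
                    "iqr": iqr,
                    "n_regions": int(vals.size),
                    "dominant_region_code": dominant,
                }
            )
    return pd.DataFrame(rows)
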