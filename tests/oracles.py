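"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route unrelated to the library's
implementation: exhaustive enumeration (spanning trees via Prüfer sequences,
accretion orders via depth-first search over all tie resolutions) or
Monte-Carlo resampling (without-replacement subsampling expectations).
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_matrix(lons, lats):
    lons = np.radians(np.asarray(lons, float))
    lats = np.radians(np.asarray(lats, float))
    h = (
        np.sin((lats[:, None] - lats[None, :]) / 2) ** 2
        + np.cos(lats[:, None]) * np.cos(lats[None, :])
        * np.sin((lons[:, None] - lons[None, :]) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _prufer_to_edges(seq, n):
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for v in seq:
        u = heapq.heappop(leaves)
        edges.append((u, v))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    u = heapq.heappop(leaves)
    w = heapq.heappop(leaves)
    edges.append((u, w))
    return edges


def brute_force_mst_total(D) -> float:
    """Minimum spanning-tree weight by enumerating all n^(n-2) labelled trees."""
    D = np.asarray(D, float)
    n = D.shape[0]
    if n == 1:
        return 0.0
    if n == 2:
        return float(D[0, 1])
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        w = sum(D[u, v] for u, v in _prufer_to_edges(seq, n))
        best = min(best, w)
    return float(best)


def exhaustive_region_sets(D, tol=1e-9):
    """All member sets reachable by the accretion rule over every start and
    every resolution of distance ties (single linkage, min over members)."""
    D = np.asarray(D, float)
    n = D.shape[0]
    results = set()

    def grow(members: frozenset, mind):
        if len(members) == n:
            return
        avail = [i for i in range(n) if i not in members]
        m = min(mind[i] for i in avail)
        for c in avail:
            if mind[c] <= m + tol:
                nm = members | {c}
                if len(nm) >= 2:
                    results.add(nm)
                new_mind = np.minimum(mind, D[c])
                grow(nm, new_mind)

    for s in range(n):
        grow(frozenset([s]), D[s].copy())
    return results


def mc_subsample_expectations(counts, m, reps, rng):
    """Monte-Carlo expectations for without-replacement subsamples of size m.

    Returns (richness_mean, richness_se, deficit_mean, deficit_se) where the
    deficit is the summed relative frequency (X_i/n in the reference sample)
    of species absent from the subsample.  The analytic expected coverage at
    size m equals ``1 - n/(n-m) * E[deficit]``, which is how the library's
    formula is checked against pure resampling.
    """
    counts = np.asarray(counts, int)
    n = int(counts.sum())
    S = counts.size
    labels = np.repeat(np.arange(S), counts)
    keys = rng.random((reps, n))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    species = labels[idx]
    presence = np.zeros((reps, S), dtype=bool)
    presence[np.repeat(np.arange(reps), m), species.ravel()] = True
    richness = presence.sum(axis=1).astype(float)
    weights = counts / n
    deficit = ((~presence) * weights).sum(axis=1)
    return (
        float(richness.mean()),
        float(richness.std(ddof=1) / np.sqrt(reps)),
        float(deficit.mean()),
        float(deficit.std(ddof=1) / np.sqrt(reps)),
    )
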