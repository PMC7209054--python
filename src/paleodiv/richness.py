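"""Sample-coverage statistics and sampling-standardized richness estimators.

All estimators operate on a *frequency vector*: per-species occurrence counts
within some pool of records (a palaeogeographical region, or the worldwide
record of one time bin).  Four estimators are provided:

``face_value``
    Observed species count; no standardization.
``sqs``
    Coverage-based rarefaction / shareholder quorum subsampling: the expected
    species richness at the sample size whose estimated coverage equals a
    target quorum ``q``.  Interpolation below the reference sample uses the
    exact hypergeometric expectations; extrapolation beyond it uses the
    standard asymptotic coverage/richness extensions driven by the singleton
    and doubleton counts.
``chao2``
    Incidence-based asymptotic extrapolator on sampling-unit presence counts
    (classical form when doubletons exist, bias-corrected otherwise).
``squares``
    Frequency-based asymptotic extrapolator
    ``S + f1^2 * sum(X_i^2) / (n^2 - f1*S)``.

Estimator failures (degenerate inputs such as all-singleton samples) are
returned as NaN values carrying an ``undefined_fallback`` flag rather than
raised, so they propagate into downstream filtering as missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "CoverageStats",
    "RichnessEstimate",
    "GCRConfig",
    "frequency_vector",
    "coverage_stats",
    "reference_coverage",
    "interpolated_richness",
    "interpolated_coverage",
    "sqs_richness",
    "chao2",
    "squares",
    "face_value",
    "gcr_sqs",
]


@dataclass(frozen=True)
class CoverageStats:
    """Frequency-based measures of sample completeness, each in [0, 1].

    ``goods_u``            1 - f1/n (Good's u).
    ``multiton_ratio``     fraction of observed species seen more than once.
    ``chao_jost_coverage`` estimated coverage of the reference sample.
    """

    goods_u: float
    multiton_ratio: float
    chao_jost_coverage: float


@dataclass(frozen=True)
class RichnessEstimate:
    estimator: str
    value: float
    params: dict = field(default_factory=dict)
    flags: frozenset = frozenset()

    @property
    def is_missing(self) -> bool:
        return not np.isfinite(self.value)


@dataclass(frozen=True)
class GCRConfig:
    """Grid-cell rarefaction: subsample occupied cells to an MST-scaled quota."""

    quota_per_1000km: int = 3
    cell_spacing_km: float = 200.0
    trials: int = 50
    rng_seed: int = 0


def frequency_vector(taxa) -> np.ndarray:
    """Per-species occurrence counts from an iterable of taxon names."""
    import pandas as pd

    return pd.Series(list(taxa)).value_counts().to_numpy()


def _validate_counts(counts):
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("frequency vector is empty")
    return x


def coverage_stats(counts) -> CoverageStats:
    x = _validate_counts(counts)
    n = x.sum()
    s_obs = x.size
    f1 = int(np.sum(x == 1))
    goods_u = 1.0 - f1 / n
    multiton = (s_obs - f1) / s_obs
    return CoverageStats(float(goods_u), float(multiton), reference_coverage(x))


def _coverage_A(n, f1, f2):
    """Deficit decay factor for reference / extrapolated coverage."""
    if f1 == 0:
        return 0.0
    if f2 > 0:
        return (n - 1) * f1 / ((n - 1) * f1 + 2 * f2)
    if f1 > 1:
        return (n - 1) * (f1 - 1) / ((n - 1) * (f1 - 1) + 2)
    return 0.0


def reference_coverage(counts) -> float:
    """Estimated coverage of the reference sample itself."""
    x = _validate_counts(counts)
    n = x.sum()
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    return float(1.0 - (f1 / n) * _coverage_A(n, f1, f2))


def _ln_choose(a, b):
    """log C(a, b) with -inf where b > a; vectorized."""
    a = np.asarray(a, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return np.where(b > a, -np.inf, out)


def interpolated_richness(counts, m) -> float:
    """Expected species count in a without-replacement subsample of size m."""
    x = _validate_counts(counts)
    n = x.sum()
    if m < 0 or m > n:
        raise ValueError("subsample size must lie in [0, n]")
    if m == 0:
        return 0.0
    ratio = np.exp(_ln_choose(n - x, m) - _ln_choose(n, m))
    return float(np.sum(1.0 - ratio))


def interpolated_coverage(counts, m) -> float:
    """Expected coverage of a without-replacement subsample of size m < n."""
    x = _validate_counts(counts)
    n = x.sum()
    if m < 0 or m >= n:
        raise ValueError("interpolated coverage requires 0 <= m < n")
    if m == 0:
        return 0.0
    ratio = np.exp(_ln_choose(n - x, m) - _ln_choose(n - 1, m))
    return float(1.0 - np.sum((x / n) * ratio))


def _f0_hat(n, f1, f2):
    if f2 > 0:
        return (n - 1) / n * f1**2 / (2 * f2)
    return (n - 1) / n * f1 * (f1 - 1) / 2


def _extrapolated_richness(x, n, s_obs, f1, f2, m_extra):
    f0 = _f0_hat(n, f1, f2)
    if f0 == 0:
        return float(s_obs)
    return float(s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** m_extra))


def _extrapolated_coverage(n, f1, f2, m_extra):
    A = _coverage_A(n, f1, f2)
    return float(1.0 - (f1 / n) * A ** (m_extra + 1))


def sqs_richness(counts, q: float) -> RichnessEstimate:
    """Coverage-standardized richness at quorum ``q`` (analytic SQS).

    The target sample size is located by monotone search on the estimated
    coverage curve; fractional sizes are resolved by linear interpolation
    between adjacent integer sizes.  Estimates requiring extrapolation beyond
    twice the reference sample are flagged ``extrapolated_beyond_2n``; samples
    consisting entirely of singletons have no defined extrapolation and return
    NaN with ``undefined_fallback``.
    """
    if not (0.0 < q < 1.0):
        raise ValueError(f"quorum must be in (0, 1), got {q}")
    x = _validate_counts(counts)
    n = int(x.sum())
    s_obs = int(x.size)
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    params = {"q": q}
    if s_obs == 1:
        return RichnessEstimate("sqs", 1.0, params)
    if f1 == n:
        return RichnessEstimate("sqs", float("nan"), params, frozenset({"undefined_fallback"}))

    c_ref = reference_coverage(x)

    def cov(m):
        if m <= 0:
            return 0.0
        if m >= n:
            return c_ref
        return interpolated_coverage(x, m)

    if abs(q - c_ref) <= 1e-12:
        return RichnessEstimate("sqs", float(s_obs), params)

    if q < c_ref:
        # monotone (binary) search for integer m with cov(m) <= q < cov(m+1)
        lo, hi = 0, n  # cov(lo) <= q, cov(hi) > q
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if cov(mid) <= q:
                lo = mid
            else:
                hi = mid
        c_lo, c_hi = cov(lo), cov(hi)
        s_lo = interpolated_richness(x, lo)
        s_hi = float(s_obs) if hi >= n else interpolated_richness(x, hi)
        t = 0.0 if c_hi == c_lo else (q - c_lo) / (c_hi - c_lo)
        return RichnessEstimate("sqs", float(s_lo + t * (s_hi - s_lo)), params)

    # extrapolation: coverage deficit shrinks geometrically with factor A
    A = _coverage_A(n, f1, f2)
    if A <= 0.0 or A >= 1.0 or f1 == 0:
        # coverage cannot be pushed above the reference value
        return RichnessEstimate(
            "sqs", float("nan"), params, frozenset({"undefined_fallback"})
        )
    m_real = np.log((1.0 - q) * n / f1) / np.log(A) - 1.0
    m_lo = max(0, int(np.floor(m_real)))
    m_hi = m_lo + 1
    c_lo = c_ref if m_lo == 0 else _extrapolated_coverage(n, f1, f2, m_lo)
    c_hi = _extrapolated_coverage(n, f1, f2, m_hi)
    s_lo = float(s_obs) if m_lo == 0 else _extrapolated_richness(x, n, s_obs, f1, f2, m_lo)
    s_hi = _extrapolated_richness(x, n, s_obs, f1, f2, m_hi)
    t = 0.0 if c_hi == c_lo else (q - c_lo) / (c_hi - c_lo)
    t = min(max(t, 0.0), 1.0)
    value = s_lo + t * (s_hi - s_lo)
    flags = set()
    if n + m_real > 2 * n:
        flags.add("extrapolated_beyond_2n")
    return RichnessEstimate("sqs", float(value), params, frozenset(flags))


def face_value(counts) -> RichnessEstimate:
    x = _validate_counts(counts)
    return RichnessEstimate("face_value", float(x.size))


def chao2(incidence_counts, n_units: int | None = None) -> RichnessEstimate:
    """Chao 2 asymptotic richness from per-species sampling-unit counts.

    ``incidence_counts[i]`` is the number of sampling units (collections by
    default in this package) in which species i occurs.  Classical form when
    doubletons are present; bias-corrected (and flagged) when q2 = 0.
    """
    y = np.asarray(incidence_counts, dtype=float)
    y = y[y > 0]
    if y.size == 0:
        raise ValueError("incidence vector is empty")
    m = int(n_units) if n_units is not None else int(y.max())
    if m < 1:
        raise ValueError("need at least one sampling unit")
    s_obs = y.size
    q1 = int(np.sum(y == 1))
    q2 = int(np.sum(y == 2))
    mult = (m - 1) / m
    flags = set()
    if q2 > 0:
        value = s_obs + mult * q1**2 / (2 * q2)
    else:
        value = s_obs + mult * q1 * (q1 - 1) / 2
        flags.add("bias_corrected")
    return RichnessEstimate("chao2", float(value), {"m": m}, frozenset(flags))


def squares(counts) -> RichnessEstimate:
    """Frequency-based 'squares' asymptotic extrapolator."""
    x = _validate_counts(counts)
    n = x.sum()
    s_obs = x.size
    f1 = int(np.sum(x == 1))
    if f1 == 0:
        return RichnessEstimate("squares", float(s_obs))
    denom = n**2 - f1 * s_obs
    if f1 == s_obs or denom <= 0:
        return RichnessEstimate(
            "squares", float("nan"), {}, frozenset({"undefined_fallback"})
        )
    value = s_obs + f1**2 * np.sum(x**2) / denom
    return RichnessEstimate("squares", float(value))


def gcr_sqs(cell_ids, taxa, mst_total_km: float, cfg: GCRConfig, q: float) -> RichnessEstimate:
    """Grid-cell-rarefied SQS.

    ``cell_ids``/``taxa`` are parallel sequences giving, for each occurrence
    in a region, its occupied cell at ``cfg.cell_spacing_km`` and its species.
    The quota of cells is ``round(quota_per_1000km * MST_km / 1000)``; regions
    with fewer occupied cells than the quota yield a missing value.  Otherwise
    the estimate is the mean SQS over ``cfg.trials`` random draws of exactly
    ``quota`` cells (occurrences pooled within each draw).
    """
    import pandas as pd

    quota = int(round(cfg.quota_per_1000km * mst_total_km / 1000.0))
    params = {"q": q, "quota": quota, "trials": cfg.trials}
    df = pd.DataFrame({"cell": list(cell_ids), "taxon": list(taxa)})
    cells = df["cell"].unique()
    if quota < 1 or len(cells) < quota:
        return RichnessEstimate(
            "sqs_gcr", float("nan"), params, frozenset({"insufficient_cells"})
        )
    rng = np.random.default_rng(cfg.rng_seed)
    values = []
    flags = set()
    for _ in range(cfg.trials):
        draw = rng.choice(cells, size=quota, replace=False)
        pooled = df[df["cell"].isin(draw)]["taxon"]
        est = sqs_richness(frequency_vector(pooled), q)
        if est.is_missing:
            flags |= set(est.flags)
            continue
        values.append(est.value)
    if not values:
        return RichnessEstimate(
            "sqs_gcr", float("nan"), params, frozenset(flags | {"undefined_fallback"})
        )
    return RichnessEstimate("sqs_gcr", float(np.mean(values)), params, frozenset(flags))
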