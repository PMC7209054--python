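"""Time-series diagnostics and diversification-model comparison.

Three questions are addressed here.  First, how much of the bin-to-bin change
in 'global' (worldwide, spatially unstandardized) richness is explained by
change in the spatial extent of sampling — quantified by ordinary least
squares on first differences of the log-transformed series.  Second, whether
spatially standardized regional diversity through time is better described by
an expansionist model (richness increasing with time) or a constrained one
(static equilibria separated by a phase shift at the end-Cretaceous mass
extinction, 66 Ma) — decided by small-sample-corrected AIC over a lattice of
five least-squares models.  Third, autocorrelation-robust versions of the
regressions via exact maximum-likelihood AR(1) generalized least squares.

AICc convention: the residual variance counts as a fitted parameter, so the
intercept-only model has k = 2.  Natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

MODEL_NAMES = ("intercept_only", "time", "time_plus_phase", "time_by_phase", "phase_only")


@dataclass(frozen=True)
class FirstDifferenceFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_differences: int


def global_timeseries(binned, bins, quorums=(0.4, 0.6, 0.8), spacings=(500.0,), grids=None):
    """Per-bin worldwide richness and spatial-sampling series.

    ``binned`` is an occurrence frame with ``bin_id``; ``bins`` the TimeBin
    list.  Returns one row per bin (empty bins give zero counts and missing
    estimates) with face-value richness, pooled-sample SQS at each quorum,
    and occupied-cell counts per spacing.
    """
    from .grid import EqualAreaGrid, count_occupied_cells
    from . import richness as rich

    if grids is None:
        grids = {s: EqualAreaGrid(s) for s in spacings}
    rows = []
    by_bin = dict(tuple(binned.groupby("bin_id")))
    for b in bins:
        sub = by_bin.get(b.bin_id)
        row = {"bin_id": b.bin_id, "midpoint_ma": b.midpoint_ma}
        if sub is None or sub.empty:
            row["n_occurrences"] = 0
            row["face_value"] = 0.0
            for q in quorums:
                row[f"sqs_q{q:g}"] = np.nan
            for s in spacings:
                row[f"occupied_cells_{s:g}"] = 0
        else:
            counts = rich.frequency_vector(sub["taxon_name"])
            row["n_occurrences"] = int(len(sub))
            row["face_value"] = float(counts.size)
            for q in quorums:
                row[f"sqs_q{q:g}"] = rich.sqs_richness(counts, q).value
            for s in spacings:
                row[f"occupied_cells_{s:g}"] = count_occupied_cells(
                    sub["paleo_lon"].to_numpy(), sub["paleo_lat"].to_numpy(), s, grids.get(s)
                )
        rows.append(row)
    return pd.DataFrame(rows)


def first_difference_fit(y, x, log_transform: bool = True, exclude=None) -> FirstDifferenceFit:
    """OLS of consecutive-bin changes in y on changes in x.

    Series must share an index ordered old -> young (e.g. bin_id); pairs with
    a missing value are dropped, as are any indices listed in ``exclude``
    (outlier bins).  With ``log_transform`` the differences are of natural
    logs, so slopes are elasticities.
    """
    df = pd.DataFrame({"y": pd.Series(y).astype(float), "x": pd.Series(x).astype(float)})
    if log_transform:
        df = df.where(df > 0)
        df = np.log(df)
    usable = df.notna().all(axis=1)
    if exclude:
        usable &= ~df.index.isin(list(exclude))
    diffs = df.diff()
    # a difference is valid only when both endpoint bins are usable; an
    # excluded or missing bin therefore removes both adjacent differences
    valid = usable & usable.shift(fill_value=False)
    dy = diffs["y"][valid]
    dx = diffs["x"][valid]
    if len(dy) < 4:
        raise ValueError("need at least 4 paired first differences")
    res = stats.linregress(dx.to_numpy(), dy.to_numpy())
    r2 = float(res.rvalue**2)
    if not np.isfinite(r2):  # zero-variance response
        r2 = 0.0
    return FirstDifferenceFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=float(res.pvalue),
        n_differences=int(len(dy)),
    )


def _aicc(rss, n, k):
    if n - k - 1 <= 0:
        return np.nan
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _design(name, t, phase):
    one = np.ones_like(t)
    if name == "intercept_only":
        return one[:, None]
    if name == "time":
        return np.column_stack([one, t])
    if name == "time_plus_phase":
        return np.column_stack([one, t, phase])
    if name == "time_by_phase":
        return np.column_stack([one, t, phase, t * phase])
    if name == "phase_only":
        return np.column_stack([one, phase])
    raise ValueError(f"unknown model {name!r}")


def fit_diversity_models(
    points: pd.DataFrame,
    response: str = "median_log_richness",
    time_col: str = "midpoint_ma",
    boundary_ma: float = 66.0,
    models=MODEL_NAMES,
) -> pd.DataFrame:
    """AICc comparison of diversification models on cluster-level diversity.

    ``points`` carries one row per cluster with the (already log-transformed)
    response and the bin midpoint in Ma.  The phase indicator is
    ``midpoint_ma < boundary_ma`` (post-extinction).  Returns a table sorted
    by AICc with ΔAICc and Akaike weights; models whose small-sample
    correction is undefined (n - k - 1 <= 0) are skipped with a flag.
    """
    df = points[[time_col, response]].dropna()
    t = df[time_col].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    phase = (t < boundary_ma).astype(float)
    n = len(y)
    rows = []
    for name in models:
        X = _design(name, t, phase)
        k = X.shape[1] + 1  # + residual variance
        if n - k - 1 <= 0 or n <= X.shape[1]:
            rows.append(
                {"model": name, "k": k, "n": n, "rss": np.nan, "loglik": np.nan,
                 "aicc": np.nan, "coefficients": None, "skipped": True}
            )
            continue
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        rss = max(rss, 1e-300)
        sigma2 = rss / n
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        rows.append(
            {"model": name, "k": k, "n": n, "rss": rss, "loglik": float(loglik),
             "aicc": float(_aicc(rss, n, k)), "coefficients": tuple(map(float, beta)),
             "skipped": False}
        )
    table = pd.DataFrame(rows)
    fitted = table[~table["skipped"]]
    best = fitted["aicc"].min()
    table["delta_aicc"] = table["aicc"] - best
    rel = np.exp(-0.5 * table["delta_aicc"]).where(~table["skipped"], 0.0).fillna(0.0)
    table["akaike_weight"] = rel / rel.sum()
    return table.sort_values("aicc").reset_index(drop=True)


@dataclass(frozen=True)
class GlsAr1Result:
    coefficients: tuple
    coefficient_se: tuple
    phi: float
    sigma2: float
    loglik: float
    aicc: float
    converged: bool


def gls_ar1_fit(y, X, add_intercept: bool = True) -> GlsAr1Result:
    """Linear model with AR(1) errors, fitted by exact maximum likelihood.

    The AR coefficient phi is profiled over (-1, 1): for each phi the data are
    whitened by the Prais–Winsten transform, the regression coefficients and
    innovation variance drop out in closed form, and the concentrated
    log-likelihood is maximized with a bounded scalar optimizer.  phi = 0
    reproduces OLS exactly.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    n, p = X.shape
    if n < 8:
        raise ValueError("need at least 8 observations")

    def whiten(phi):
        w = np.sqrt(1.0 - phi**2)
        yw = np.empty_like(y)
        Xw = np.empty_like(X)
        yw[0] = w * y[0]
        Xw[0] = w * X[0]
        yw[1:] = y[1:] - phi * y[:-1]
        Xw[1:] = X[1:] - phi * X[:-1]
        return yw, Xw

    def profile(phi):
        yw, Xw = whiten(phi)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        rss = max(float(resid @ resid), 1e-300)
        sigma2 = rss / n
        # exact Gaussian AR(1) log-likelihood, concentrated over beta, sigma2
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + 0.5 * np.log(1.0 - phi**2)
        return loglik, beta, sigma2, Xw

    res = optimize.minimize_scalar(
        lambda phi: -profile(phi)[0], bounds=(-0.999, 0.999), method="bounded",
        options={"xatol": 1e-8},
    )
    converged = bool(res.success)
    phi = float(res.x)
    loglik, beta, sigma2, Xw = profile(phi)
    k = p + 2  # + phi + sigma2
    aicc = -2 * loglik + 2 * k + (2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.nan)
    XtX_inv = np.linalg.pinv(Xw.T @ Xw)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * (float(sigma2) * n / max(n - p, 1)), 0, None))
    return GlsAr1Result(
        coefficients=tuple(map(float, beta)),
        coefficient_se=tuple(map(float, se)),
        phi=phi,
        sigma2=float(sigma2),
        loglik=float(loglik),
        aicc=float(aicc),
        converged=converged,
    )


def interval_slope_test(points: pd.DataFrame, early_ma: float, late_ma: float,
                        response: str = "median_log_richness", time_col: str = "midpoint_ma"):
    """OLS slope of log richness on time within [late_ma, early_ma], with t-test.

    Returns ``(slope, p_value, n_points)``; fewer than 5 in-interval points is
    an error.
    """
    df = points[[time_col, response]].dropna()
    sel = df[(df[time_col] <= early_ma) & (df[time_col] >= late_ma)]
    if len(sel) < 5:
        raise ValueError(f"need at least 5 points in [{late_ma}, {early_ma}] Ma, got {len(sel)}")
    res = stats.linregress(sel[time_col].to_numpy(), sel[response].to_numpy())
    return float(res.slope), float(res.pvalue), int(len(sel))
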