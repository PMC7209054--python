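"""Reading, validating, cleaning and time-binning of fossil occurrence tables.

The canonical in-memory container is a pandas DataFrame with one row per
occurrence and the columns in :data:`CANONICAL_COLUMNS`.  Input CSVs in the
Paleobiology Database (PBDB) export dialect are mapped onto these columns via
a dialect dictionary (source column -> canonical name); other dialects can be
supplied by the caller.

Cleaning removes records by higher-taxon tag (e.g. flying tetrapods whose
record is Lagerstätten-dominated), by environment, and by identification rank;
binning assigns each record to the ~10-Myr composite interval that contains
strictly more than half of its stratigraphic age range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical column order for occurrence tables
CANONICAL_COLUMNS = [
    "occurrence_id",
    "collection_id",
    "taxon_name",
    "taxon_rank",
    "paleo_lon",
    "paleo_lat",
    "max_ma",
    "min_ma",
    "reference_id",
    "region_code",
    "environment",
    "group_tags",
]

MANDATORY = [
    "occurrence_id",
    "collection_id",
    "taxon_name",
    "taxon_rank",
    "paleo_lon",
    "paleo_lat",
    "max_ma",
    "min_ma",
    "reference_id",
]

#: PBDB download column names -> canonical names
PBDB_DIALECT = {
    "occurrence_no": "occurrence_id",
    "collection_no": "collection_id",
    "accepted_name": "taxon_name",
    "accepted_rank": "taxon_rank",
    "paleolng": "paleo_lon",
    "paleolat": "paleo_lat",
    "max_ma": "max_ma",
    "min_ma": "min_ma",
    "reference_no": "reference_id",
    "cc": "region_code",
    "environment": "environment",
    "group_tags": "group_tags",
}

#: flying tetrapods -- inadequate, Lagerstätten-dominated fossil record
DEFAULT_EXCLUDED_TAGS = frozenset({"Aves", "Pterosauromorpha", "Chiroptera"})
DEFAULT_EXCLUDED_ENVIRONMENTS = frozenset({"marine"})
DEFAULT_ALLOWED_RANKS = frozenset({"species", "subspecies"})


@dataclass(frozen=True)
class ExclusionConfig:
    excluded_group_tags: frozenset = DEFAULT_EXCLUDED_TAGS
    excluded_environments: frozenset = DEFAULT_EXCLUDED_ENVIRONMENTS
    allowed_ranks: frozenset = DEFAULT_ALLOWED_RANKS
    drop_missing_paleocoords: bool = True


def tags_to_set(value) -> frozenset:
    """Parse a ';'-delimited tag string (or NaN) into a frozenset."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    s = str(value).strip()
    if not s:
        return frozenset()
    return frozenset(t.strip() for t in s.split(";") if t.strip())


def read_occurrences(path, dialect: dict | None = None):
    """Read an occurrence CSV, returning ``(frame, report)``.

    Rows with unparseable or out-of-bounds coordinates/ages are dropped and
    counted in the report.  A missing mandatory column is a hard error naming
    the source column.
    """
    dialect = dict(PBDB_DIALECT if dialect is None else dialect)
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"occurrence file {path} is empty")
    if raw.empty:
        raise ValueError(f"occurrence file {path} contains no rows")
    inverse = {canonical: src for src, canonical in dialect.items()}
    for canonical in MANDATORY:
        src = inverse.get(canonical, canonical)
        if src not in raw.columns:
            raise ValueError(f"mandatory column {src!r} missing from {path}")
    df = raw.rename(columns=dialect)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df = df[CANONICAL_COLUMNS].copy()
    report = {"n_input": int(len(df))}

    for col in ("paleo_lon", "paleo_lat", "max_ma", "min_ma"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad_numeric = df[["paleo_lon", "paleo_lat", "max_ma", "min_ma"]].isna().any(axis=1)
    report["dropped_unparseable"] = int(bad_numeric.sum())
    df = df[~bad_numeric]

    oob = (
        (df["paleo_lon"].abs() > 180.0)
        | (df["paleo_lat"].abs() > 90.0)
        | (df["max_ma"] < df["min_ma"])
        | (df["min_ma"] < 0)
    )
    report["dropped_invalid"] = int(oob.sum())
    df = df[~oob]

    empty_name = df["taxon_name"].fillna("").str.strip() == ""
    report["dropped_unnamed"] = int(empty_name.sum())
    df = df[~empty_name]

    df["taxon_rank"] = df["taxon_rank"].fillna("").str.strip().str.lower()
    report["n_retained"] = int(len(df))
    return df.reset_index(drop=True), report


def clean_occurrences(df: pd.DataFrame, config: ExclusionConfig | None = None):
    """Apply taxon-tag / environment / rank exclusions.

    Returns ``(survivors, tallies)``; tallies count removals per rule with
    each record attributed to the first rule that matched it.  Idempotent.
    """
    cfg = config if config is not None else ExclusionConfig()
    tags = df["group_tags"].map(tags_to_set)
    by_tag = tags.map(lambda t: bool(t & cfg.excluded_group_tags))
    env = df["environment"].fillna("").str.strip().str.lower()
    excluded_env = {e.lower() for e in cfg.excluded_environments}
    by_env = env.isin(excluded_env) & ~by_tag
    if cfg.allowed_ranks:
        allowed = {r.lower() for r in cfg.allowed_ranks}
        by_rank = ~df["taxon_rank"].isin(allowed) & ~by_tag & ~by_env
    else:
        by_rank = pd.Series(False, index=df.index)
    removed = by_tag | by_env | by_rank
    tallies = {
        "removed_by_group_tag": int(by_tag.sum()),
        "removed_by_environment": int(by_env.sum()),
        "removed_by_rank": int(by_rank.sum()),
    }
    out = df[~removed].reset_index(drop=True)
    if out.empty and not df.empty:
        warnings.warn("cleaning removed every occurrence", stacklevel=2)
    return out, tallies


@dataclass(frozen=True)
class TimeBin:
    bin_id: str
    early_ma: float
    late_ma: float

    def __post_init__(self):
        if not self.early_ma > self.late_ma:
            raise ValueError(f"bin {self.bin_id}: early_ma must exceed late_ma")

    @property
    def midpoint_ma(self) -> float:
        return 0.5 * (self.early_ma + self.late_ma)

    @property
    def length_myr(self) -> float:
        return self.early_ma - self.late_ma


def make_bin_table(oldest_ma: float, youngest_ma: float = 0.0, length_myr: float = 10.0):
    """Contiguous equal-length bins from ``oldest_ma`` down to ``youngest_ma``."""
    if oldest_ma <= youngest_ma:
        raise ValueError("oldest_ma must exceed youngest_ma")
    n = int(round((oldest_ma - youngest_ma) / length_myr))
    bins = []
    for i in range(n):
        early = oldest_ma - i * length_myr
        late = max(youngest_ma, early - length_myr)
        bins.append(TimeBin(f"bin_{early:g}_{late:g}", early, late))
    validate_bins(bins)
    return bins


def validate_bins(bins):
    """Bins must be ordered old -> young and non-overlapping."""
    for a, b in zip(bins, bins[1:]):
        if b.early_ma > a.late_ma + 1e-9:
            raise ValueError(f"bins {a.bin_id} and {b.bin_id} overlap or are unordered")


def assign_time_bins(df: pd.DataFrame, bins):
    """Assign records to the unique bin holding >50% of their age range.

    Zero-length ranges go to the bin containing the point age; a point exactly
    on a bin boundary goes to the older bin (geologic boundary-age convention).
    Returns ``(frame_with_bin_id, n_dropped)``.
    """
    validate_bins(bins)
    max_ma = df["max_ma"].to_numpy(dtype=float)
    min_ma = df["min_ma"].to_numpy(dtype=float)
    early = np.array([b.early_ma for b in bins])
    late = np.array([b.late_ma for b in bins])
    span = max_ma - min_ma

    # overlap of each record with each bin: (n_bins, n_records)
    ov = np.maximum(
        0.0,
        np.minimum(max_ma[None, :], early[:, None]) - np.maximum(min_ma[None, :], late[:, None]),
    )
    assigned = np.full(len(df), -1, dtype=int)

    ranged = span > 0
    if ranged.any():
        frac = ov[:, ranged] / span[ranged][None, :]
        best = np.argmax(frac, axis=0)
        ok = frac[best, np.arange(frac.shape[1])] > 0.5
        idx = np.flatnonzero(ranged)
        assigned[idx[ok]] = best[ok]

    point = ~ranged
    if point.any():
        a = max_ma[point]
        contains = (late[:, None] <= a[None, :]) & (a[None, :] <= early[:, None])
        any_bin = contains.any(axis=0)
        # older bin = smaller bin index (bins ordered old -> young)
        first = np.argmax(contains, axis=0)
        idx = np.flatnonzero(point)
        assigned[idx[any_bin]] = first[any_bin]

    out = df.copy()
    out["bin_id"] = [bins[i].bin_id if i >= 0 else "" for i in assigned]
    dropped = int(np.sum(assigned < 0))
    out = out[out["bin_id"] != ""].reset_index(drop=True)
    return out, dropped
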