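"""Reading, validating and pivoting rating and gold-label tables.

On-disk formats are plain UTF-8 CSV with fixed lowercase headers:

* ratings:  ``worker,picture,dimension,rating,population,batch``
  (``population`` and ``batch`` optional; default ``"all"`` / empty),
* gold:     ``picture,dimension,mean,sd,n``.

Ratings are integers on the 9-point SAM scale.  Missing cells in the
pivoted items x raters matrix are ``NaN`` and are never imputed here;
complete-case policy belongs to the ICC layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptySelectionError, SchemaError, ValidationError

DIMENSIONS = ("valence", "arousal", "dominance")
RATING_MIN, RATING_MAX = 1, 9
NEUTRAL = 5

_RATING_COLUMNS = ["worker", "picture", "dimension", "rating", "population", "batch"]
_GOLD_COLUMNS = ["picture", "dimension", "mean", "sd", "n"]


@dataclass
class RatingsTable:
    """Long-format table of individual worker ratings.

    ``records`` has columns worker, picture, dimension, rating,
    population, batch (strings except the integer rating).
    """

    records: pd.DataFrame
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    @property
    def dimensions(self) -> list[str]:
        return list(self.records["dimension"].unique())

    @property
    def populations(self) -> list[str]:
        return list(self.records["population"].unique())


@dataclass
class RatingsMatrix:
    """Items x raters grid for one dimension (and population slice).

    ``values`` is a float array with NaN marking cells the rater did
    not fill in.  Row order follows first appearance of the picture in
    the source table, column order first appearance of the worker.
    """

    values: np.ndarray
    items: list[str]
    raters: list[str]
    dimension: str
    population: str = "all"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_nonmissing(self) -> int:
        return int(np.isfinite(self.values).sum())


@dataclass
class GoldTable:
    """Reference (gold) labels: per (picture, dimension) mean, sd, n."""

    entries: pd.DataFrame

    def lookup(self, dimension: str) -> pd.DataFrame:
        sub = self.entries[self.entries["dimension"] == dimension]
        if sub.empty:
            raise EmptySelectionError(f"no gold entries for dimension {dimension!r}")
        return sub.set_index("picture")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ReadSummary:
    """Row bookkeeping for lenient reads."""

    n_read: int = 0
    n_dropped: int = 0
    reasons: list[str] = field(default_factory=list)


def _normalize_ratings_frame(df: pd.DataFrame, path: str) -> pd.DataFrame:
    missing = {"worker", "picture", "dimension", "rating"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    out = pd.DataFrame()
    for col in ("worker", "picture", "dimension"):
        out[col] = df[col].astype(str)
    out["rating"] = df["rating"]
    out["population"] = (
        df["population"].astype(str).replace({"nan": "all", "": "all"})
        if "population" in df.columns
        else "all"
    )
    out["batch"] = (
        df["batch"].astype(str).replace({"nan": ""}) if "batch" in df.columns else ""
    )
    return out


def validate_records(
    df: pd.DataFrame, strict: bool = True
) -> tuple[pd.DataFrame, ReadSummary]:
    """Apply the rating-record invariants to a normalized frame.

    Strict mode raises on the first violation; lenient mode drops
    offending rows and counts them in the returned summary.
    """
    summary = ReadSummary(n_read=len(df))
    bad = pd.Series(False, index=df.index)

    numeric = pd.to_numeric(df["rating"], errors="coerce")
    nonint = numeric.isna() | (numeric != numeric.round())
    out_of_range = ~nonint & ((numeric < RATING_MIN) | (numeric > RATING_MAX))
    bad_dim = ~df["dimension"].isin(DIMENSIONS)
    dup = df.duplicated(subset=["worker", "picture", "dimension"], keep="first")

    for mask, reason in (
        (nonint, "non-integer rating"),
        (out_of_range, f"rating outside [{RATING_MIN}, {RATING_MAX}]"),
        (bad_dim, "unknown dimension"),
        (dup, "duplicate (worker, picture, dimension)"),
    ):
        if mask.any():
            if strict:
                row = int(np.flatnonzero(mask.to_numpy())[0])
                raise ValidationError(f"row {row}: {reason}")
            summary.reasons.extend([reason] * int(mask.sum()))
            bad |= mask

    summary.n_dropped = int(bad.sum())
    clean = df[~bad].copy()
    clean["rating"] = pd.to_numeric(clean["rating"]).astype(int)
    return clean.reset_index(drop=True), summary


def read_ratings(path, strict: bool = True) -> RatingsTable:
    """Read a ratings CSV, validating the 9-point-scale invariants.

    With ``strict`` off, invalid rows are dropped; the drop count is
    attached to the table's ``provenance`` string and available via
    ``read_ratings_with_summary``.
    """
    table, _ = read_ratings_with_summary(path, strict=strict)
    return table


def read_ratings_with_summary(path, strict: bool = True) -> tuple[RatingsTable, ReadSummary]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = _normalize_ratings_frame(df, str(path))
    clean, summary = validate_records(df, strict=strict)
    prov = f"{path}"
    if summary.n_dropped:
        prov += f" ({summary.n_dropped} invalid rows dropped)"
    return RatingsTable(records=clean, provenance=prov), summary


def write_ratings(table: RatingsTable, path):
    """Write a ratings table as CSV; inverse of :func:`read_ratings`."""
    out = table.records.reindex(columns=_RATING_COLUMNS)
    out.to_csv(path, index=False)
    return path


def read_gold(path) -> GoldTable:
    """Read a gold-label CSV (per picture x dimension mean/sd/n)."""
    df = pd.read_csv(path)
    missing = set(_GOLD_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing gold column(s) {sorted(missing)}")
    df = df[_GOLD_COLUMNS].copy()
    df["picture"] = df["picture"].astype(str)
    df["dimension"] = df["dimension"].astype(str)
    if df.duplicated(subset=["picture", "dimension"]).any():
        dupes = df[df.duplicated(subset=["picture", "dimension"], keep=False)]
        raise SchemaError(
            f"duplicate gold keys: {sorted(set(zip(dupes['picture'], dupes['dimension'])))[:5]}"
        )
    if ((df["mean"] < RATING_MIN) | (df["mean"] > RATING_MAX)).any():
        raise ValidationError("gold mean outside the [1, 9] rating scale")
    if (df["sd"] < 0).any():
        raise ValidationError("gold sd must be >= 0")
    if (df["n"] < 1).any():
        raise ValidationError("gold n must be a positive rater count")
    return GoldTable(entries=df.reset_index(drop=True))


def write_gold(gold: GoldTable, path):
    gold.entries.reindex(columns=_GOLD_COLUMNS).to_csv(path, index=False)
    return path


def pivot_matrix(
    table: RatingsTable, dimension: str, population: str = "all"
) -> RatingsMatrix:
    """Pivot long records into an items x raters grid with NaN holes.

    Row/column order follows first appearance in the filtered records,
    so the pivot is deterministic for a given table.
    """
    df = table.records
    mask = df["dimension"] == dimension
    if population != "all":
        mask &= df["population"] == population
    sub = df[mask]
    if sub.empty:
        raise EmptySelectionError(
            f"no records for dimension={dimension!r}, population={population!r}"
        )
    item_codes, items = pd.factorize(sub["picture"])
    rater_codes, raters = pd.factorize(sub["worker"])
    values = np.full((len(items), len(raters)), np.nan)
    values[item_codes, rater_codes] = sub["rating"].to_numpy(dtype=float)
    return RatingsMatrix(
        values=values,
        items=list(items),
        raters=list(raters),
        dimension=dimension,
        population=population,
    )
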