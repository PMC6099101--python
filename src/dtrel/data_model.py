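"""Domain tables, validation, and CSV I/O for crossed rating designs.

The package analyses ratings of divergent-thinking responses collected in a
fully crossed person x item x rater design.  Two table layouts occur:

``response level``
    one row per individual response a person gave to an item, per rater:
    ``person_id, family, item_id, rater_id, response_id, rating``.

``score level``
    one row per (person, item, rater) cell holding a single score (an
    averaged rating or a holistic "snapshot" rating):
    ``person_id, family, item_id, rater_id, score``.

Ratings and scores live on the 1-5 scale used by the raters.  Task family
(Alternative Uses vs. Consequences) is a partition, never a modelled facet:
every downstream analysis runs separately within each family's subtable.
Identifiers are opaque strings.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "FAMILIES",
    "RESPONSE_COLUMNS",
    "SCORE_COLUMNS",
    "FLUENCY_COLUMNS",
    "RATING_MIN",
    "RATING_MAX",
    "Design",
    "SchemaError",
    "RatingValidationError",
    "load_ratings",
    "load_item_family_map",
    "write_table",
    "validate_response_table",
    "validate_score_table",
    "validate_balanced",
]

FAMILIES = ("alternative_uses", "consequences")

RESPONSE_COLUMNS = ["person_id", "family", "item_id", "rater_id", "response_id", "rating"]
SCORE_COLUMNS = ["person_id", "family", "item_id", "rater_id", "score"]
FLUENCY_COLUMNS = ["person_id", "family", "item_id", "fluency"]

RATING_MIN = 1.0
RATING_MAX = 5.0

_ID_COLS = {
    "response_level": ["person_id", "item_id", "rater_id", "response_id"],
    "score_level": ["person_id", "item_id", "rater_id"],
}
_VALUE_COL = {"response_level": "rating", "score_level": "score"}


class SchemaError(ValueError):
    """A required column is missing or the layout is unknown."""


class RatingValidationError(ValueError):
    """Row-level contents violate the table invariants."""


@dataclass(frozen=True)
class Design:
    """Facet sample sizes of a crossed person x item x rater table.

    ``balanced`` is true iff every (person, item, rater) cell holds exactly
    one score; G-study estimation requires a balanced design with at least
    two levels per facet.
    """

    n_p: int
    n_i: int
    n_r: int
    balanced: bool

    def require_gstudy(self) -> None:
        if not self.balanced:
            raise RatingValidationError(
                "G-study estimation requires a balanced complete design; "
                "this table has empty (person, item, rater) cells. "
                "Unbalanced data would need an REML estimator (see docs/methods.md)."
            )
        if min(self.n_p, self.n_i, self.n_r) < 2:
            raise RatingValidationError(
                f"need >= 2 levels per facet to separate interactions, got "
                f"n_p={self.n_p}, n_i={self.n_i}, n_r={self.n_r}"
            )


def _check_columns(df: pd.DataFrame, required: list[str]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


def _check_ratings(values: pd.Series, column: str, bounds: bool = True) -> None:
    numeric = pd.to_numeric(values, errors="coerce")
    bad = numeric.isna()
    if bounds:
        bad |= (numeric < RATING_MIN) | (numeric > RATING_MAX)
    if bad.any():
        idx = int(bad.idxmax())
        expected = f"a number in [{RATING_MIN:g}, {RATING_MAX:g}]" if bounds else "a number"
        raise RatingValidationError(
            f"{column} {values.loc[idx]!r} at row {idx} is not {expected}"
        )


def _check_family(df: pd.DataFrame) -> None:
    unknown = set(df["family"].unique()) - set(FAMILIES)
    if unknown:
        raise RatingValidationError(
            f"unknown task family value(s) {sorted(unknown)}; expected one of {FAMILIES}"
        )
    per_item = df.groupby("item_id", sort=False)["family"].nunique()
    conflicted = per_item[per_item > 1]
    if not conflicted.empty:
        raise RatingValidationError(
            f"item(s) mapped to more than one family: {list(conflicted.index)}"
        )


def _validate(df: pd.DataFrame, layout: str, bounds: bool = True) -> pd.DataFrame:
    value_col = _VALUE_COL[layout]
    required = RESPONSE_COLUMNS if layout == "response_level" else SCORE_COLUMNS
    _check_columns(df, required)
    df = df.loc[:, required].copy()
    for col in required:
        if col != value_col:
            df[col] = df[col].astype(str)
    _check_ratings(df[value_col], value_col, bounds=bounds)
    df[value_col] = pd.to_numeric(df[value_col])
    _check_family(df)
    dupes = df.duplicated(subset=_ID_COLS[layout])
    if dupes.any():
        key = df.loc[dupes.idxmax(), _ID_COLS[layout]].tolist()
        raise RatingValidationError(f"duplicate {_ID_COLS[layout]} tuple: {key}")
    return df.reset_index(drop=True)


def validate_response_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a response-level ratings table."""
    return _validate(df, "response_level")


def validate_score_table(df: pd.DataFrame, bounds: bool = False) -> pd.DataFrame:
    """Validate and normalise a score-level table (one score per cell row).

    Scale bounds are not enforced here by default: in-memory score tables
    may be continuous model draws (the untruncated simulator) or rescaled
    diagnostics.  Bounds are always enforced when rating-scale data enters
    from a file (:func:`load_ratings`).
    """
    return _validate(df, "score_level", bounds=bounds)


def load_item_family_map(path: str | Path) -> dict[str, str]:
    """Read an item -> family map from a YAML/JSON-style config file."""
    import yaml

    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise SchemaError(f"{path}: expected a mapping of item_id to family")
    out = {str(k): str(v) for k, v in mapping.items()}
    bad = {k: v for k, v in out.items() if v not in FAMILIES}
    if bad:
        raise RatingValidationError(f"item map assigns unknown families: {bad}")
    return out


def load_ratings(
    path: str | Path,
    layout: str = "response_level",
    item_family_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Load a ratings CSV and return the validated long-format table.

    Parameters
    ----------
    path
        CSV file with a header row (UTF-8, comma separated).
    layout
        ``"response_level"`` or ``"score_level"``.
    item_family_map
        Optional item_id -> family mapping.  If the file lacks a ``family``
        column the map is required; if both are present they must agree.
    """
    if layout not in _ID_COLS:
        raise SchemaError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, dtype=str)
    if "family" not in df.columns:
        if item_family_map is None:
            raise SchemaError("missing required column(s): family (or supply an item->family map)")
        df["family"] = df["item_id"].astype(str).map(dict(item_family_map))
        if df["family"].isna().any():
            orphan = sorted(df.loc[df["family"].isna(), "item_id"].unique())
            raise RatingValidationError(f"item(s) absent from the item->family map: {orphan}")
    elif item_family_map is not None:
        mapped = df["item_id"].astype(str).map(dict(item_family_map))
        clash = mapped.notna() & (mapped != df["family"].astype(str))
        if clash.any():
            raise RatingValidationError(
                f"family column disagrees with the item->family map at row {int(clash.idxmax())}"
            )
    return _validate(df, layout)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any package table as a plain UTF-8 CSV (round-trip safe)."""
    df.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


def validate_balanced(scores: pd.DataFrame) -> Design:
    """Check completeness of a score table and return its :class:`Design`.

    Balanced means every (person, item, rater) combination appears exactly
    once.  Duplicated cells raise; missing cells yield ``balanced=False`` so
    estimation entry points can refuse the table with a useful message.
    """
    if scores.empty:
        raise RatingValidationError("score table is empty")
    counts = scores.groupby(["person_id", "item_id", "rater_id"], sort=False).size()
    if (counts > 1).any():
        cell = counts[counts > 1].index[0]
        raise RatingValidationError(f"duplicated (person, item, rater) cell: {cell}")
    n_p = scores["person_id"].nunique()
    n_i = scores["item_id"].nunique()
    n_r = scores["rater_id"].nunique()
    return Design(n_p=n_p, n_i=n_i, n_r=n_r, balanced=len(counts) == n_p * n_i * n_r)
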