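"""The three divergent-thinking scoring systems: average rating, snapshot, fluency.

* **Average rating** — every individual response gets a 1-5 rating from every
  rater; a person's score per item and rater is the unweighted mean of that
  rater's ratings over the person's responses to the item.
* **Snapshot** — each rater awards a single holistic 1-5 rating to a person's
  whole response set for an item; no aggregation is needed.
* **Fluency** — the count of responses a person produced for an item; raters
  play no role.

Composite per-person scores (mean over raters, optionally then over the items
of a task family) feed the convergent-validity analysis.
"""

from __future__ import annotations

import pandas as pd

from .data_model import (
    FLUENCY_COLUMNS,
    RatingValidationError,
    validate_response_table,
    validate_score_table,
)

__all__ = [
    "average_rating_scores",
    "snapshot_scores",
    "fluency_scores",
    "composite_scores",
]


def _require_crossed(responses: pd.DataFrame) -> None:
    # every (person, item) must be rated by the same full set of raters,
    # otherwise the averaged scores no longer form a crossed design
    raters = set(responses["rater_id"].unique())
    seen = responses.groupby(["person_id", "item_id"])["rater_id"].agg(set)
    partial = seen[seen != raters]
    if not partial.empty:
        cell = partial.index[0]
        raise RatingValidationError(
            f"(person, item) {cell} is rated by {sorted(partial.iloc[0])} "
            f"but the table has raters {sorted(raters)}; the averaged scores "
            "would not form a crossed design"
        )


def average_rating_scores(responses: pd.DataFrame) -> pd.DataFrame:
    """Collapse response-level ratings to one mean score per (person, item, rater).

    Each response carries equal weight regardless of how many responses the
    person gave (no per-category weighting, no de-duplication).
    """
    responses = validate_response_table(responses)
    if responses.empty:
        raise RatingValidationError("response table is empty")
    _require_crossed(responses)
    scores = (
        responses.groupby(["person_id", "family", "item_id", "rater_id"], sort=True)["rating"]
        .mean()
        .reset_index()
        .rename(columns={"rating": "score"})
    )
    return scores


def snapshot_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Validate a snapshot table and pass it through unchanged.

    Snapshot scoring yields exactly one holistic rating per (person, item,
    rater) cell by construction, so there is nothing to aggregate; this
    enforces the one-row-per-cell definition and cell uniqueness (scale
    bounds are enforced whenever the table enters from a file).
    """
    scores = validate_score_table(scores)
    counts = scores.groupby(["person_id", "item_id", "rater_id"], sort=False).size()
    if (counts > 1).any():
        cell = counts[counts > 1].index[0]
        raise RatingValidationError(
            f"snapshot scoring awards one rating per (person, item, rater); "
            f"cell {cell} has {counts[counts > 1].iloc[0]} rows"
        )
    return scores.reset_index(drop=True)


def fluency_scores(responses: pd.DataFrame) -> pd.DataFrame:
    """Count distinct responses per (person, item).

    Persons present in the table but missing an item get fluency 0 for that
    item, so the output covers the full person x item grid.
    """
    responses = validate_response_table(responses)
    counts = (
        responses.groupby(["person_id", "family", "item_id"], sort=True)["response_id"]
        .nunique()
        .reset_index()
        .rename(columns={"response_id": "fluency"})
    )
    # complete the person x item grid with zero counts
    items = responses[["item_id", "family"]].drop_duplicates()
    grid = pd.MultiIndex.from_product(
        [sorted(responses["person_id"].unique()), sorted(items["item_id"])],
        names=["person_id", "item_id"],
    ).to_frame(index=False)
    grid = grid.merge(items, on="item_id")
    out = grid.merge(counts, on=["person_id", "family", "item_id"], how="left")
    out["fluency"] = out["fluency"].fillna(0).astype(int)
    return out.sort_values(["person_id", "item_id"]).reset_index(drop=True)[FLUENCY_COLUMNS]


def composite_scores(
    scores: pd.DataFrame | None = None,
    fluency: pd.DataFrame | None = None,
    level: str = "per_item",
    system: str = "average",
) -> pd.DataFrame:
    """Build per-person composite variables for the validity analysis.

    Parameters
    ----------
    scores
        Score-level table (average-rating or snapshot scores).
    fluency
        Fluency table; included as its own set of variables when given.
    level
        ``"per_item"`` — person score per item = mean over raters (fluency is
        already per item); ``"per_family"`` — those per-item scores averaged
        over the items of each task family.
    system
        Label prefix for the score variables (e.g. ``"average"``,
        ``"snapshot"``).

    Returns
    -------
    DataFrame with columns ``person_id, variable_name, value``, one row per
    (person, variable); variable names look like ``average_brick`` or
    ``fluency_alternative_uses``.
    """
    if level not in ("per_item", "per_family"):
        raise ValueError(f"unknown level {level!r}; expected 'per_item' or 'per_family'")
    pieces = []
    if scores is not None:
        scores = validate_score_table(scores)
        per_item = (
            scores.groupby(["person_id", "family", "item_id"], sort=True)["score"]
            .mean()
            .reset_index()
        )
        if level == "per_item":
            per_item["variable_name"] = system + "_" + per_item["item_id"]
            pieces.append(per_item.rename(columns={"score": "value"}))
        else:
            per_family = (
                per_item.groupby(["person_id", "family"], sort=True)["score"].mean().reset_index()
            )
            per_family["variable_name"] = system + "_" + per_family["family"]
            pieces.append(per_family.rename(columns={"score": "value"}))
    if fluency is not None:
        if level == "per_item":
            flu = fluency.copy()
            flu["variable_name"] = "fluency_" + flu["item_id"].astype(str)
            pieces.append(flu.rename(columns={"fluency": "value"}))
        else:
            flu = (
                fluency.groupby(["person_id", "family"], sort=True)["fluency"]
                .mean()
                .reset_index()
            )
            flu["variable_name"] = "fluency_" + flu["family"]
            pieces.append(flu.rename(columns={"fluency": "value"}))
    if not pieces:
        raise ValueError("provide scores and/or fluency")
    out = pd.concat([p[["person_id", "variable_name", "value"]] for p in pieces])
    return out.sort_values(["variable_name", "person_id"]).reset_index(drop=True)
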