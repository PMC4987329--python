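"""Percentile group formation from Likert ratings.

Images are rated on a 7-point scale by several raters; for each material
property the images with the lowest and highest quarter of mean ratings form
the "low" and "high" groups used by every downstream classifier (84 images at
fraction 0.25 give 21 images per group).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import List

import numpy as np
import pandas as pd

__all__ = [
    "PropertyGroups",
    "validate_ratings",
    "mean_ratings",
    "form_groups",
    "load_ratings",
]

RATING_COLUMNS = ("image_id", "property", "rater", "score")


@dataclass
class PropertyGroups:
    """Low- and high-rating image groups for one property."""

    property: str
    low_ids: List[str]
    high_ids: List[str]
    cutoff_low: float
    cutoff_high: float

    def __post_init__(self) -> None:
        if set(self.low_ids) & set(self.high_ids):
            raise ValueError("low and high groups overlap")

    @property
    def n(self) -> int:
        return len(self.low_ids)

    @property
    def all_ids(self) -> List[str]:
        return list(self.low_ids) + list(self.high_ids)

    def labels(self) -> pd.Series:
        """Map image_id -> 'low' / 'high' for group members."""
        return pd.Series(
            {**{i: "low" for i in self.low_ids},
             **{i: "high" for i in self.high_ids}},
            name=self.property,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PropertyGroups":
        with open(path) as fh:
            return cls(**json.load(fh))


def validate_ratings(table: pd.DataFrame) -> pd.DataFrame:
    """Check rating-table schema and the 1..7 integer score range."""
    missing = set(RATING_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"rating table is missing columns: {sorted(missing)}")
    scores = table["score"]
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")
    if (scores < 1).any() or (scores > 7).any() or (scores != scores.round()).any():
        raise ValueError("scores must be integers in [1, 7]")
    return table


def load_ratings(path) -> pd.DataFrame:
    """Read a ratings CSV (columns image_id, property, rater, score)."""
    return validate_ratings(pd.read_csv(path))


def mean_ratings(table: pd.DataFrame, property: str) -> pd.Series:
    """Arithmetic mean score over raters, per image, for one property.

    Every image must be rated by every rater; gaps are reported explicitly.
    """
    validate_ratings(table)
    sub = table[table["property"] == property]
    if sub.empty:
        raise ValueError(f"property {property!r} not present in rating table")
    pivot = sub.pivot_table(index="image_id", columns="rater", values="score",
                            aggfunc="first")
    if pivot.isna().any().any():
        gaps = [(img, rater)
                for img, row in pivot.iterrows()
                for rater, v in row.items() if pd.isna(v)]
        raise ValueError(f"missing ratings for (image, rater) pairs: {gaps[:20]}")
    return pivot.mean(axis=1).rename(property)


def form_groups(means: pd.Series, fraction: float = 0.25,
                property: str | None = None) -> PropertyGroups:
    """Split images into low/high groups at the given rating percentile.

    The lowest ``round(n * fraction)`` images by mean rating form the low
    group and the highest form the high group (round-half-away-from-zero, so
    84 images at 0.25 give exactly 21).  Ties at a boundary are broken by a
    stable sort on image_id, which makes group membership deterministic.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError(f"fraction must be in (0, 0.5], got {fraction} "
                         "(groups would overlap)")
    n = len(means)
    g = int(np.floor(n * fraction + 0.5))
    if g < 1:
        raise ValueError(f"group size would be 0 for n={n}, fraction={fraction}")
    if 2 * g > n:
        raise ValueError(f"groups of {g} overlap for n={n}")
    order = means.rename("mean").reset_index()
    order.columns = ["image_id", "mean"]
    order = order.sort_values(["mean", "image_id"], kind="mergesort")
    low = order.head(g)["image_id"].tolist()
    high = order.tail(g)["image_id"].tolist()
    return PropertyGroups(
        property=property or (means.name or "property"),
        low_ids=low,
        high_ids=high,
        cutoff_low=float(np.quantile(means.to_numpy(), fraction)),
        cutoff_high=float(np.quantile(means.to_numpy(), 1.0 - fraction)),
    )
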