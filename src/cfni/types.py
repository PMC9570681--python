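"""Core domain types shared across the pipeline.

The unit of analysis is the *client cart*: the full set of food items one
food-pantry client selects during one visit.  Each physical food is a
:class:`FoodItem` carrying (a) the per-serving nutrients that drive its
stoplight tier (saturated fat, sodium, added sugar) and (b) the dietary
constituent totals that feed HEI-2015 scoring.
"""
from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .errors import ValidationError

#: The 11 food categories of the HER (Healthy Eating Research) guidelines.
CATEGORIES = (
    "fruits_vegetables",
    "grains",
    "protein",
    "dairy",
    "non_dairy_alternatives",
    "beverages",
    "mixed_dishes",
    "snacks",
    "desserts",
    "condiments_cooking_staples",
    "miscellaneous",
)

#: Categories excluded from tier ranking (condiments, cooking staples,
#: miscellaneous items such as baby food).
NOT_RANKED_CATEGORIES = ("condiments_cooking_staples", "miscellaneous")

GRAMS_PER_POUND = 453.59237


class Tier(enum.Enum):
    """Stoplight tier of a single food: green (choose often), yellow
    (choose sometimes), red (choose rarely), or not ranked.

    GREEN < YELLOW < RED orders severity; NOT_RANKED is incomparable and
    excluded from cart-level measures.
    """

    GREEN = 0
    YELLOW = 1
    RED = 2
    NOT_RANKED = -1

    @property
    def severity(self) -> int:
        if self is Tier.NOT_RANKED:
            raise ValueError("NOT_RANKED has no severity")
        return self.value


#: Constituent field names, in canonical order. Units: energy kcal; fruit /
#: vegetable / dairy cup-equivalents; grain / protein ounce-equivalents;
#: fatty acids grams; sodium milligrams; added sugar grams.
CONSTITUENT_FIELDS = (
    "energy",
    "total_fruit",
    "whole_fruit",
    "total_veg",
    "greens_beans",
    "dairy",
    "whole_grain",
    "refined_grain",
    "total_protein",
    "seafood_plant_protein",
    "mufa",
    "pufa",
    "sfa",
    "sodium",
    "added_sugar",
)


@dataclass(frozen=True)
class ConstituentTotals:
    """Dietary constituent totals for an item or a whole cart.

    Additive: cart totals are the component-wise sum over items.  All HEI
    densities are ratios of these totals (never per-item averages).
    """

    energy: float = 0.0
    total_fruit: float = 0.0
    whole_fruit: float = 0.0
    total_veg: float = 0.0
    greens_beans: float = 0.0
    dairy: float = 0.0
    whole_grain: float = 0.0
    refined_grain: float = 0.0
    total_protein: float = 0.0
    seafood_plant_protein: float = 0.0
    mufa: float = 0.0
    pufa: float = 0.0
    sfa: float = 0.0
    sodium: float = 0.0
    added_sugar: float = 0.0

    def __post_init__(self) -> None:
        for f in CONSTITUENT_FIELDS:
            v = getattr(self, f)
            if v < 0:
                raise ValidationError(f"constituent '{f}' must be non-negative, got {v}")

    def __add__(self, other: "ConstituentTotals") -> "ConstituentTotals":
        return ConstituentTotals(
            **{f: getattr(self, f) + getattr(other, f) for f in CONSTITUENT_FIELDS}
        )

    def scaled(self, factor: float) -> "ConstituentTotals":
        return ConstituentTotals(
            **{f: getattr(self, f) * factor for f in CONSTITUENT_FIELDS}
        )


@dataclass(frozen=True)
class FoodItem:
    """One physical food in a cart.

    ``weight`` is the mass in pounds (strictly positive).  The three
    ``*_per_serving`` nutrients determine the stoplight tier via
    category-specific thresholds; ``constituents`` are totals for the whole
    item quantity and feed HEI scoring.
    """

    item_id: str
    cart_id: str
    category: str
    weight: float
    sat_fat_per_serving: float
    sodium_per_serving: float
    added_sugar_per_serving: float
    constituents: ConstituentTotals = field(default_factory=ConstituentTotals)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown category '{self.category}'; allowed: {', '.join(CATEGORIES)}"
            )
        if not self.weight > 0:
            raise ValidationError(f"weight must be strictly positive, got {self.weight}")
        for name in ("sat_fat_per_serving", "sodium_per_serving", "added_sugar_per_serving"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative, got {getattr(self, name)}")


@dataclass(frozen=True)
class Cart:
    """A non-empty ordered collection of :class:`FoodItem` sharing one cart id."""

    cart_id: str
    items: tuple[FoodItem, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValidationError(f"cart '{self.cart_id}' is empty")
        for it in self.items:
            if it.cart_id != self.cart_id:
                raise ValidationError(
                    f"item '{it.item_id}' has cart_id '{it.cart_id}' != '{self.cart_id}'"
                )

    def __iter__(self) -> Iterator[FoodItem]:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class TierSummary:
    """Percent-by-weight tier composition of a cart's ranked food.

    The three percentages are computed on ranked weight only (not-ranked
    food removed from numerator and denominator) and sum to 100.
    """

    cart_id: str
    pct_green: float
    pct_yellow: float
    pct_red: float
    ranked_weight: float
    excluded_weight: float

    def __post_init__(self) -> None:
        if self.ranked_weight > 0:
            total = self.pct_green + self.pct_yellow + self.pct_red
            if abs(total - 100.0) > 1e-9:
                raise ValidationError(
                    f"tier percentages must sum to 100, got {total!r} for cart {self.cart_id}"
                )
        for name in ("pct_green", "pct_yellow", "pct_red"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 100 + 1e-9:
                raise ValidationError(f"{name}={v} outside [0, 100]")


@dataclass(frozen=True)
class HEIScore:
    """A cart's HEI-2015 total (0-100) with its 13 component scores."""

    cart_id: str
    component_scores: dict[str, float]
    total: float

    def __post_init__(self) -> None:
        if abs(self.total - sum(self.component_scores.values())) > 1e-9:
            raise ValidationError("HEI total must equal the sum of component scores")
        if not -1e-9 <= self.total <= 100 + 1e-9:
            raise ValidationError(f"HEI total {self.total} outside [0, 100]")


@dataclass(frozen=True)
class FittedLinearModel:
    """A fitted model predicting HEI from %green and %red.

    ``method`` identifies the estimator: ridge with information-criterion
    penalty selection, ridge with cross-validated penalty, or OLS.
    ``penalty`` is the ridge lambda (0 for OLS).  ``diagnostics`` keeps the
    selection trace (criterion or CV curve over the lambda grid).
    """

    method: str
    coef_green: float
    coef_red: float
    constant: float
    penalty: float
    diagnostics: dict = field(default_factory=dict, compare=False)

    def predict(self, pct_green, pct_red):
        """Predicted HEI for compositions (vectorized)."""
        import numpy as np

        g = np.asarray(pct_green, dtype=float)
        r = np.asarray(pct_red, dtype=float)
        return self.constant + self.coef_green * g + self.coef_red * r


@dataclass(frozen=True)
class IndexFormula:
    """The three-variable 0-100 index: weighted tier percentages, shifted
    and rescaled so the all-green cart scores 100 and the all-red cart 0.

    ``offset = 100 * min(weights)`` and ``scale = 100 * (max - min)`` are the
    theoretical extremes of the weighted sum over the composition simplex.
    """

    coef_green_3v: float
    coef_yellow_3v: float
    coef_red_3v: float
    offset: float
    scale: float

    def weights(self) -> tuple[float, float, float]:
        return (self.coef_green_3v, self.coef_yellow_3v, self.coef_red_3v)


@dataclass(frozen=True)
class QuintileProfile:
    """Mean tier composition within HEI quintiles, plus linear trend tests.

    ``means`` maps quintile label (1 = lowest HEI) to a dict with count and
    mean tier percentages; ``trends`` maps each tier variable to
    (slope per quintile step, two-sided p-value).
    """

    means: dict[int, dict[str, float]]
    trends: dict[str, tuple[float, float]]


@dataclass(frozen=True)
class CVResult:
    """K-fold cross-validated correlation between index and HEI."""

    fold_sizes: tuple[int, ...]
    fold_correlations: tuple[float, ...]
    mean_r: float
    sd_r: float
    method: str
    seed: int

    def __post_init__(self) -> None:
        if len(self.fold_sizes) != len(self.fold_correlations):
            raise ValidationError("fold_sizes and fold_correlations length mismatch")
        mean = sum(self.fold_correlations) / len(self.fold_correlations)
        if abs(mean - self.mean_r) > 1e-12:
            raise ValidationError("mean_r must equal the mean of fold_correlations")


def as_dict(obj) -> dict:
    """Recursively convert a domain dataclass to plain Python containers."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: as_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, enum.Enum):
        return obj.name
    if isinstance(obj, dict):
        return {k: as_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [as_dict(v) for v in obj]
    return obj
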