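"""Stoplight tier ranking of foods and percent-by-weight cart summaries.

The HER guidelines assign each food a green / yellow / red tier from
category-specific per-serving thresholds on saturated fat, sodium and added
sugar; condiments, cooking staples and miscellaneous items are not ranked.
A cart is then summarized by the percentage by weight of green, yellow and
red foods among its *ranked* items — not-ranked food is removed from both
numerator and denominator before any cart-level measure.

Threshold values are configuration data, not code: :func:`load_thresholds`
reads a YAML file with one block per category giving ``green_max`` /
``yellow_max`` cutoffs per nutrient.  Cutoff comparisons are inclusive
("no more than" semantics): a value exactly at ``green_max`` is green.
An item's tier is the *worst* per-nutrient tier — a single disqualifying
nutrient decides the stoplight rank.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import AnalysisError, ConfigurationError, DegenerateCartError
from .types import CATEGORIES, Cart, FoodItem, Tier, TierSummary

logger = logging.getLogger(__name__)

#: nutrient keys used in threshold configs, matched to FoodItem fields
NUTRIENT_FIELDS = {
    "sat_fat_g": "sat_fat_per_serving",
    "sodium_mg": "sodium_per_serving",
    "added_sugar_g": "added_sugar_per_serving",
}


@dataclass(frozen=True)
class NutrientCutoffs:
    """Inclusive per-serving cutoffs: green iff value <= green_max, yellow
    iff value <= yellow_max, red otherwise."""

    green_max: float
    yellow_max: float

    def __post_init__(self) -> None:
        if self.green_max > self.yellow_max:
            raise ConfigurationError(
                f"green_max ({self.green_max}) must not exceed yellow_max ({self.yellow_max})"
            )

    def tier(self, value: float) -> Tier:
        if value <= self.green_max:
            return Tier.GREEN
        if value <= self.yellow_max:
            return Tier.YELLOW
        return Tier.RED


@dataclass(frozen=True)
class CategoryThresholds:
    """Ranking rule for one food category.

    ``cutoffs`` maps nutrient key -> :class:`NutrientCutoffs`; a nutrient
    absent from the mapping has no threshold in this category and is
    skipped.  ``ranked=False`` marks the whole category as not ranked.
    """

    ranked: bool
    cutoffs: Mapping[str, NutrientCutoffs]


@dataclass(frozen=True)
class TierThresholds:
    """Complete thresholds configuration: one rule per category."""

    categories: Mapping[str, CategoryThresholds]

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORIES if c not in self.categories]
        if missing:
            raise ConfigurationError(f"thresholds config missing categories: {missing}")

    def for_category(self, category: str) -> CategoryThresholds:
        try:
            return self.categories[category]
        except KeyError:
            raise ConfigurationError(f"no thresholds configured for category '{category}'")


def load_thresholds(path) -> TierThresholds:
    """Read a thresholds YAML file.

    Layout::

        categories:
          grains:
            ranked: true
            sat_fat_g: {green_max: 2.0, yellow_max: 5.0}
            sodium_mg: {green_max: 230, yellow_max: 480}
            added_sugar_g: {green_max: 6.0, yellow_max: 12.0}
          condiments_cooking_staples:
            ranked: false
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "categories" not in raw:
        raise ConfigurationError("thresholds config must have a top-level 'categories' map")
    cats = {}
    for name, block in raw["categories"].items():
        if name not in CATEGORIES:
            raise ConfigurationError(f"unknown category '{name}' in thresholds config")
        ranked = bool(block.get("ranked", True))
        cutoffs = {}
        for key in NUTRIENT_FIELDS:
            if key in block and block[key] is not None:
                spec = block[key]
                cutoffs[key] = NutrientCutoffs(
                    green_max=float(spec["green_max"]), yellow_max=float(spec["yellow_max"])
                )
        cats[name] = CategoryThresholds(ranked=ranked, cutoffs=cutoffs)
    return TierThresholds(categories=cats)


def rank_item(item: FoodItem, thresholds: TierThresholds) -> Tier:
    """Tier of a single food: NOT_RANKED for unranked categories, otherwise
    the worst per-nutrient tier across saturated fat, sodium, added sugar."""
    rule = thresholds.for_category(item.category)
    if not rule.ranked:
        return Tier.NOT_RANKED
    worst = Tier.GREEN
    for key, cut in rule.cutoffs.items():
        t = cut.tier(getattr(item, NUTRIENT_FIELDS[key]))
        if t.severity > worst.severity:
            worst = t
    return worst


def summarize_cart(cart: Cart, thresholds: TierThresholds) -> TierSummary:
    """Percent-by-weight tier composition of a cart's ranked food.

    Raises
    ------
    DegenerateCartError
        If every item in the cart is not-ranked (zero ranked weight).
    """
    weights = {Tier.GREEN: 0.0, Tier.YELLOW: 0.0, Tier.RED: 0.0}
    excluded = 0.0
    for item in cart:
        tier = rank_item(item, thresholds)
        if tier is Tier.NOT_RANKED:
            excluded += item.weight
        else:
            weights[tier] += item.weight
    ranked_weight = sum(weights.values())
    if ranked_weight <= 0:
        raise DegenerateCartError(
            f"cart '{cart.cart_id}' has no ranked food (excluded weight {excluded:.3f} lb)"
        )
    return TierSummary(
        cart_id=cart.cart_id,
        pct_green=100.0 * weights[Tier.GREEN] / ranked_weight,
        pct_yellow=100.0 * weights[Tier.YELLOW] / ranked_weight,
        pct_red=100.0 * weights[Tier.RED] / ranked_weight,
        ranked_weight=ranked_weight,
        excluded_weight=excluded,
    )


def filter_ranked_items(cart: Cart, thresholds: TierThresholds) -> Cart | None:
    """Copy of ``cart`` with not-ranked items removed; None if nothing remains."""
    kept = tuple(i for i in cart if rank_item(i, thresholds) is not Tier.NOT_RANKED)
    if not kept:
        return None
    return Cart(cart_id=cart.cart_id, items=kept)


def summarize_collection(
    carts: Iterable[Cart], thresholds: TierThresholds
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cart tier summaries plus unweighted means and sample SDs.

    Degenerate carts (only not-ranked food) are excluded with a logged
    warning, mirroring the removal of not-ranked items before analysis.

    Returns
    -------
    (summaries, stats)
        ``summaries``: one row per non-degenerate cart with columns
        cart_id, pct_green, pct_yellow, pct_red, ranked_weight,
        excluded_weight.  ``stats``: rows ``mean`` and ``sd`` over the three
        percentage columns (sample SD, n-1 denominator).
    """
    rows = []
    for cart in carts:
        try:
            s = summarize_cart(cart, thresholds)
        except DegenerateCartError as exc:
            logger.warning("excluding degenerate cart: %s", exc)
            continue
        rows.append(s)
    if not rows:
        raise AnalysisError("all carts are degenerate (no ranked food anywhere)")
    summaries = pd.DataFrame(
        {
            "cart_id": [s.cart_id for s in rows],
            "pct_green": [s.pct_green for s in rows],
            "pct_yellow": [s.pct_yellow for s in rows],
            "pct_red": [s.pct_red for s in rows],
            "ranked_weight": [s.ranked_weight for s in rows],
            "excluded_weight": [s.excluded_weight for s in rows],
        }
    )
    pct = summaries[["pct_green", "pct_yellow", "pct_red"]]
    stats = pd.DataFrame({"mean": pct.mean(), "sd": pct.std(ddof=1)}).T
    return summaries, stats
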