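import numpy as np
import pytest

from cfni.hei import HEIComponentStandard
from cfni.ranker import CategoryThresholds, NutrientCutoffs, TierThresholds
from cfni.types import CATEGORIES, Cart, ConstituentTotals, FoodItem


def make_item(
    item_id="i1",
    cart_id="A",
    category="grains",
    weight=1.0,
    sat_fat=0.0,
    sodium=0.0,
    sugar=0.0,
    totals=None,
    **constituents,
):
    """Build a FoodItem; ``sat_fat``/``sodium``/``sugar`` are the per-serving
    ranking nutrients.  Constituent totals come from ``totals`` (dict or
    ConstituentTotals) or from extra keywords — use ``totals`` when the
    constituent name (e.g. sodium) collides with a ranking nutrient."""
    if totals is not None:
        constituents = totals if isinstance(totals, dict) else None
        if constituents is None:
            return FoodItem(
                item_id=item_id, cart_id=cart_id, category=category, weight=weight,
                sat_fat_per_serving=sat_fat, sodium_per_serving=sodium,
                added_sugar_per_serving=sugar, constituents=totals,
            )
    return FoodItem(
        item_id=item_id,
        cart_id=cart_id,
        category=category,
        weight=weight,
        sat_fat_per_serving=sat_fat,
        sodium_per_serving=sodium,
        added_sugar_per_serving=sugar,
        constituents=ConstituentTotals(**constituents),
    )


@pytest.fixture
def toy_thresholds():
    """Explicit toy cutoffs: every ranked category shares the grains rule
    (sat fat 2/5 g, sodium 230/480 mg, sugar 6/12 g per serving)."""
    cutoffs = {
        "sat_fat_g": NutrientCutoffs(2.0, 5.0),
        "sodium_mg": NutrientCutoffs(230.0, 480.0),
        "added_sugar_g": NutrientCutoffs(6.0, 12.0),
    }
    cats = {}
    for c in CATEGORIES:
        ranked = c not in ("condiments_cooking_staples", "miscellaneous")
        cats[c] = CategoryThresholds(ranked=ranked, cutoffs=cutoffs if ranked else {})
    return TierThresholds(categories=cats)


@pytest.fixture
def toy_standards():
    """Two hand-checkable components: a 10-point moderation standard
    (full <= 6.5% energy, zero >= 26%) and a 5-point adequacy standard
    (full at 0.8 cup eq / 1000 kcal)."""
    return (
        HEIComponentStandard(
            name="added_sugars",
            constituent="added_sugar",
            max_points=10,
            kind="moderation",
            basis="percent_energy",
            energy_per_gram=4.0,
            standard_for_max=6.5,
            standard_for_min=26.0,
        ),
        HEIComponentStandard(
            name="total_fruits",
            constituent="total_fruit",
            max_points=5,
            kind="adequacy",
            basis="per_1000_kcal",
            standard_for_max=0.8,
            standard_for_min=0.0,
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20220921)
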