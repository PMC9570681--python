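"""Rank a small cart into stoplight tiers and summarize it by weight.

Each food is assigned green / yellow / red from per-serving saturated fat,
sodium and added sugar against its category's thresholds; condiments are
not ranked and are excluded from the percentages.
"""
from cfni import Cart, FoodItem, load_thresholds, rank_item, summarize_cart
from cfni.io import default_thresholds_path

thresholds = load_thresholds(default_thresholds_path())

items = (
    FoodItem("apples", "demo", "fruits_vegetables", weight=3.0,
             sat_fat_per_serving=0.0, sodium_per_serving=0.0,
             added_sugar_per_serving=0.0),
    FoodItem("canned-soup", "demo", "mixed_dishes", weight=2.0,
             sat_fat_per_serving=2.0, sodium_per_serving=520.0,
             added_sugar_per_serving=1.0),
    FoodItem("cookies", "demo", "desserts", weight=1.0,
             sat_fat_per_serving=4.0, sodium_per_serving=150.0,
             added_sugar_per_serving=14.0),
    FoodItem("cooking-oil", "demo", "condiments_cooking_staples", weight=1.0,
             sat_fat_per_serving=2.0, sodium_per_serving=0.0,
             added_sugar_per_serving=0.0),
)
cart = Cart("demo", items)

for item in cart:
    print(f"{item.item_id:12s} {item.category:28s} -> {rank_item(item, thresholds).name}")

s = summarize_cart(cart, thresholds)
print(f"\n%green={s.pct_green:.1f}  %yellow={s.pct_yellow:.1f}  %red={s.pct_red:.1f}")
print(f"ranked weight {s.ranked_weight:.1f} lb, excluded {s.excluded_weight:.1f} lb")
# The oil is not ranked, so percentages are over the 6 lb of ranked food:
# 3 lb green apples (50%), 2 lb yellow soup (33.3%), 1 lb red cookies (16.7%).
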