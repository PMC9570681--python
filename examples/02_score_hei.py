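"""Score a cart with the HEI-2015 engine.

Constituent amounts are summed over the cart and converted to densities
(per 1000 kcal, percent of energy, or the unsaturated:saturated fat
ratio), then each of the 13 components is scored piecewise-linearly
against its standards and summed into the 0-100 total.
"""
from cfni import Cart, ConstituentTotals, FoodItem, load_standards, score_cart
from cfni.io import default_standards_path

standards = load_standards(default_standards_path())

cart = Cart("demo", (
    FoodItem("produce-box", "demo", "fruits_vegetables", weight=4.0,
             sat_fat_per_serving=0, sodium_per_serving=10, added_sugar_per_serving=0,
             constituents=ConstituentTotals(
                 energy=600, total_fruit=2.0, whole_fruit=1.5, total_veg=3.0,
                 greens_beans=0.8, sodium=200)),
    FoodItem("rice-and-beans", "demo", "mixed_dishes", weight=2.0,
             sat_fat_per_serving=1, sodium_per_serving=300, added_sugar_per_serving=0,
             constituents=ConstituentTotals(
                 energy=900, whole_grain=1.0, refined_grain=2.0, total_protein=3.0,
                 seafood_plant_protein=2.0, mufa=6, pufa=4, sfa=3, sodium=1200)),
    FoodItem("snack-mix", "demo", "snacks", weight=1.0,
             sat_fat_per_serving=3, sodium_per_serving=250, added_sugar_per_serving=9,
             constituents=ConstituentTotals(
                 energy=700, refined_grain=2.0, mufa=8, pufa=5, sfa=6,
                 sodium=900, added_sugar=30)),
))

score = score_cart(cart, standards)
for name, points in score.component_scores.items():
    print(f"{name:28s} {points:6.2f}")
print(f"{'TOTAL':28s} {score.total:6.2f}")
# The total is the cart's alignment with the dietary guidelines on the
# usual 0-100 scale; component rows show where points were lost (here
# mostly dairy, whole grains, and total protein foods).
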