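# Default stoplight tier thresholds, per serving, by food category.
# version: cfni-default-1 (SWAP-aligned charitable-food cutoffs)
#
# Cutoffs are inclusive upper bounds: value <= green_max -> green,
# value <= yellow_max -> yellow, else red. A nutrient omitted from a
# category has no threshold there and is skipped. Condiments / cooking
# staples and miscellaneous foods are not ranked.
#
# These defaults follow the published guideline structure (saturated fat g,
# sodium mg, added sugar g per serving, category-specific); sites adopting a
# specific guideline revision should supply their own file with the same
# layout via --config.
categories:
  fruits_vegetables:
    ranked: true
    sat_fat_g: {green_max: 2.0, yellow_max: 5.0}
    sodium_mg: {green_max: 140.0, yellow_max: 480.0}
    added_sugar_g: {green_max: 6.0, yellow_max: 12.0}
  grains:
    ranked: true
    sat_fat_g: {green_max: 2.0, yellow_max: 5.0}
    sodium_mg: {green_max: 230.0, yellow_max: 480.0}
    added_sugar_g: {green_max: 6.0, yellow_max: 12.0}
  protein:
    ranked: true
    sat_fat_g: {green_max: 2.0, yellow_max: 5.0}
    sodium_mg: {green_max: 230.0, yellow_max: 480.0}
    added_sugar_g: {green_max: 6.0, yellow_max: 12.0}
  dairy:
    ranked: true
    sat_fat_g: {green_max: 3.0, yellow_max: 6.0}
    sodium_mg: {green_max: 230.0, yellow_max: 480.0}
    added_sugar_g: {green_max: 6.0, yellow_max: 12.0}
  non_dairy_alternatives:
    ranked: true
    sat_fat_g: {green_max: 2.0, yellow_max: 5.0}
    sodium_mg: {green_max: 230.0, yellow_max: 480.0}
    added_sugar_g: {green_max: 6.0, yellow_max: 12.0}
  beverages:
    ranked: true
    sat_fat_g: {green_max: 2.0, yellow_max: 5.0}
    sodium_mg: {green_max: 140.0, yellow_max: 230.0}
    added_sugar_g: {green_max: 0.0, yellow_max: 12.0}
  mixed_dishes:
    ranked: true
    sat_fat_g: {green_max: 3.0, yellow_max: 6.0}
    sodium_mg: {green_max: 480.0, yellow_max: 600.0}
    added_sugar_g: {green_max: 6.0, yellow_max: 12.0}
  snacks:
    ranked: true
    sat_fat_g: {green_max: 2.0, yellow_max: 5.0}
    sodium_mg: {green_max: 230.0, yellow_max: 480.0}
    added_sugar_g: {green_max: 6.0, yellow_max: 12.0}
  desserts:
    ranked: true
    sat_fat_g: {green_max: 2.0, yellow_max: 5.0}
    sodium_mg: {green_max: 230.0, yellow_max: 480.0}
    added_sugar_g: {green_max: 6.0, yellow_max: 12.0}
  condiments_cooking_staples:
    ranked: false
  miscellaneous:
    ranked: false
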