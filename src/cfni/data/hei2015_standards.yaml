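# HEI-2015 component scoring standards.
#
# 13 components, max points summing to 100. Densities:
#   per_1000_kcal     amount * 1000 / energy(kcal)
#   percent_energy    amount(g) * energy_per_gram * 100 / energy(kcal)
#   fatty_acid_ratio  (mufa + pufa) / sfa
#
# Adequacy components score max_points at densities at/above
# standard_for_max, 0 at/below standard_for_min, linear between.
# Moderation components score max_points at/below standard_for_max,
# 0 at/above standard_for_min, linear between.
components:
  - name: total_fruits
    constituent: total_fruit
    max_points: 5
    kind: adequacy
    basis: per_1000_kcal
    standard_for_max: 0.8     # cup eq / 1000 kcal
    standard_for_min: 0.0
  - name: whole_fruits
    constituent: whole_fruit
    max_points: 5
    kind: adequacy
    basis: per_1000_kcal
    standard_for_max: 0.4
    standard_for_min: 0.0
  - name: total_vegetables
    constituent: total_veg
    max_points: 5
    kind: adequacy
    basis: per_1000_kcal
    standard_for_max: 1.1
    standard_for_min: 0.0
  - name: greens_and_beans
    constituent: greens_beans
    max_points: 5
    kind: adequacy
    basis: per_1000_kcal
    standard_for_max: 0.2
    standard_for_min: 0.0
  - name: whole_grains
    constituent: whole_grain
    max_points: 10
    kind: adequacy
    basis: per_1000_kcal
    standard_for_max: 1.5     # oz eq / 1000 kcal
    standard_for_min: 0.0
  - name: dairy
    constituent: dairy
    max_points: 10
    kind: adequacy
    basis: per_1000_kcal
    standard_for_max: 1.3
    standard_for_min: 0.0
  - name: total_protein_foods
    constituent: total_protein
    max_points: 5
    kind: adequacy
    basis: per_1000_kcal
    standard_for_max: 2.5
    standard_for_min: 0.0
  - name: seafood_and_plant_proteins
    constituent: seafood_plant_protein
    max_points: 5
    kind: adequacy
    basis: per_1000_kcal
    standard_for_max: 0.8
    standard_for_min: 0.0
  - name: fatty_acids
    constituent: null           # uses mufa, pufa, sfa
    max_points: 10
    kind: adequacy
    basis: fatty_acid_ratio
    standard_for_max: 2.5
    standard_for_min: 1.2
  - name: refined_grains
    constituent: refined_grain
    max_points: 10
    kind: moderation
    basis: per_1000_kcal
    standard_for_max: 1.8
    standard_for_min: 4.3
  - name: sodium
    constituent: sodium
    max_points: 10
    kind: moderation
    basis: per_1000_kcal
    standard_for_max: 1100.0    # mg / 1000 kcal (= 1.1 g)
    standard_for_min: 2000.0
  - name: added_sugars
    constituent: added_sugar
    max_points: 10
    kind: moderation
    basis: percent_energy
    energy_per_gram: 4.0
    standard_for_max: 6.5       # % of energy
    standard_for_min: 26.0
  - name: saturated_fats
    constituent: sfa
    max_points: 10
    kind: moderation
    basis: percent_energy
    energy_per_gram: 9.0
    standard_for_max: 8.0
    standard_for_min: 16.0
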