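# Reference configuration: every value shown here is the shipped default,
# so an empty config file is equivalent to this one.  Override any subset.
#
# Nutrition bounds are weekly totals for a 5-lunch week following the K-5
# lunch meal pattern; daily quantities are enforced at the weekly level.
nutrition:
  week_length: 5
  energy_min_kcal: 2750.0        # 550 kcal per lunch
  energy_max_kcal: 3250.0        # 650 kcal per lunch
  sodium_max_mg: 6150.0          # 1230 mg per lunch
  saturated_fat_max_frac_energy: 0.10
  fruit_min_cup: 2.5
  total_veg_min_cup: 3.75
  veg_subgroup_min_cup:
    dark_green: 0.5
    red_orange: 0.75
    beans_peas: 0.5
    starchy: 0.5
    other: 0.5
  grains_min_oz: 8.0
  grains_max_oz: 10.0
  meat_alt_min_oz: 8.0
  meat_alt_max_oz: 10.0
  milk_min_cup: 5.0
  entree_count: 5
  fruit_count: 5
  milk_count: 5
  vegetable_count_min: 5
  vegetable_count_max: 10        # up to two vegetables per day

budget: 6.70                     # USD per weekly menu (1.34 per lunch)

repetition:
  per_item:
    entree: 1
    fruit: 2
    vegetable: 2
    milk: 5
  protein_subcategory_limit: 2
  flavor_subcategory_limit: 2

# HEI-2015 cut-points.  Densities are per 1000 kcal unless kind says
# otherwise; added sugars / saturated fats are % of energy; fatty acids is
# the (PUFA+MUFA)/SFA ratio.
hei:
  total_fruit:           {max_score: 5,  min_standard: 0.0, max_standard: 0.8,  direction: adequacy}
  whole_fruit:           {max_score: 5,  min_standard: 0.0, max_standard: 0.4,  direction: adequacy}
  total_veg:             {max_score: 5,  min_standard: 0.0, max_standard: 1.1,  direction: adequacy}
  greens_beans:          {max_score: 5,  min_standard: 0.0, max_standard: 0.2,  direction: adequacy}
  whole_grains:          {max_score: 10, min_standard: 0.0, max_standard: 1.5,  direction: adequacy}
  dairy:                 {max_score: 10, min_standard: 0.0, max_standard: 1.3,  direction: adequacy}
  total_protein:         {max_score: 5,  min_standard: 0.0, max_standard: 2.5,  direction: adequacy}
  seafood_plant_protein: {max_score: 5,  min_standard: 0.0, max_standard: 0.8,  direction: adequacy}
  fatty_acids:           {max_score: 10, min_standard: 1.2, max_standard: 2.5,  direction: adequacy, kind: fat_ratio}
  refined_grains:        {max_score: 10, min_standard: 1.8, max_standard: 4.3,  direction: moderation}
  sodium:                {max_score: 10, min_standard: 1.1, max_standard: 2.0,  direction: moderation}
  added_sugars:          {max_score: 10, min_standard: 6.5, max_standard: 26.0, direction: moderation, kind: percent_energy}
  saturated_fats:        {max_score: 10, min_standard: 8.0, max_standard: 16.0, direction: moderation, kind: percent_energy}

# Multi-objective goal values default to the ideal point (each single
# objective's own optimum).  Override a goal value like so:
# goals:
#   cost: {value: 6.00}
goals: {}
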