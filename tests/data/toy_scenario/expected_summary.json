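{
  "_comment": "Hand-computed expectations for the 2x2-grid, 2-unit, 5-day toy scenario. Fire field: east-column cells carry 40 and 50 ug/m3 on days 1,3,4,5; zero elsewhere. East unit daily fire means: 45,0,45,45,45; west all zero. With smokewave threshold 35 / min 3 consecutive days, east has one episode (days 3-5, peak 45). Fixed breaks 0.34/0.56/0.86 put west (mean 0) in class 1, east (mean 36) in class 4.",
  "domain_fire_mean": 18.0,
  "domain_all_mean": 26.7,
  "domain_percent_attributable": 67.41573033707866,
  "unit_period_fire_mean": {"west": 0.0, "east": 36.0},
  "unit_period_all_mean": {"west": 9.2, "east": 44.2},
  "unit_percent_attributable": {"west": 0.0, "east": 81.44796380090497},
  "unit_classes": {"west": 1, "east": 4},
  "unit_smokewave_totals": {"west": 0, "east": 1},
  "cell_smokewave_totals": {"col0": 0, "col1_row0": 1, "col1_row1": 1},
  "at_risk": {
    "class_1": {"births": 100.0, "total_population_millions": 1.0},
    "class_4": {"births": 300.0, "total_population_millions": 3.0},
    "total": {"births": 400.0, "total_population_millions": 4.0}
  },
  "fraction_above_min_class_2_percent": {"births": 75.0, "total_population_millions": 75.0},
  "smokewave_population": {
    "min_1_population": 3.0, "min_1_percent": 75.0,
    "min_2_population": 0.0, "min_2_percent": 0.0
  }
}
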