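# Population size at risk by county annual-mean fire-PM2.5 exposure class,
# California 2007-2013. Class intervals are lower-open/upper-closed on
# annual-mean fire-PM2.5 (ug/m3) with quartile breaks 0.34/0.56/0.86 and
# observed max 20.3. Population-type columns are millions of persons
# (2007-2013 average); event columns are counts. "missing" is the county
# reported without model data (no cell centroid inside its boundary).
row,interval,asthma_ed_visits,births,heart_attack_hosp,poverty_millions,under_18_millions,over_65_millions,total_population_millions
total,,2908,591359,1574,13.67,10.60,4.67,36.78
class_1,"(0.00, 0.34]",677,241761,350,5.73,4.44,1.92,17.45
class_2,"(0.34, 0.56]",489,84170,235,1.85,1.52,0.65,5.87
class_3,"(0.56, 0.86]",626,141995,336,3.37,2.52,1.08,9.77
class_4,"(0.86, 20.3]",1079,114496,634,2.49,2.02,0.91,7.87
missing,,38,8936,20,0.22,0.11,0.11,0.80
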