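# Statewide mean daily PM2.5 (ug/m3) for 12-km grid cells within California,
# 2007-2013, from the paired CMAQ runs (all emission sources vs. no-fire).
# "period" is the 2007-2013 average row. Standard deviations in parentheses
# in the published table are carried as *_sd columns.
year,all_sources_mean,all_sources_sd,fire_mean,fire_sd
2007,4.62,2.27,0.87,1.55
2008,8.90,8.76,4.40,8.89
2009,4.77,1.50,0.61,0.91
2010,4.60,1.51,0.31,0.47
2011,3.90,1.43,0.50,0.70
2012,3.84,1.51,0.71,1.16
2013,3.74,1.94,1.16,1.89
period,4.91,4.04,1.22,3.78
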