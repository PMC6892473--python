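# Annual mean observed vs. model-predicted PM2.5 carbon (organic+elemental,
# ug/m3) at rural IMPROVE monitor locations in California, stratified by
# predicted wildland-fire impact (> 0.34 ug/m3 fire carbon = wildfire_impacted;
# <= 0.34 = little_or_no). n is matched monitor-day pairs.
stratum,year,n,mean_observed,mean_predicted
wildfire_impacted,2007,463,4.1,4.5
wildfire_impacted,2008,721,5.2,7.1
wildfire_impacted,2009,422,5.6,3.5
wildfire_impacted,2010,220,3.8,3.0
wildfire_impacted,2011,428,3.5,3.2
wildfire_impacted,2012,418,3.9,3.7
wildfire_impacted,2013,589,3.7,5.3
little_or_no,2007,918,1.6,1.1
little_or_no,2008,599,1.5,1.5
little_or_no,2009,966,1.4,1.2
little_or_no,2010,1158,1.4,1.2
little_or_no,2011,947,1.3,1.0
little_or_no,2012,1008,1.3,1.0
little_or_no,2013,776,1.2,0.7
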