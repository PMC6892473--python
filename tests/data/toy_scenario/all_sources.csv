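# origin_x=0 origin_y=0 cell_size=10 n_cols=2 n_rows=2 crs_label=local-planar source_label=all_sources
date,row,col,value
2007-01-01,0,0,10
2007-01-01,0,1,50
2007-01-01,1,0,20
2007-01-01,1,1,60
2007-01-02,0,0,10
2007-01-02,0,1,10
2007-01-02,1,0,10
2007-01-02,1,1,10
2007-01-03,0,0,5
2007-01-03,0,1,45
2007-01-03,1,0,5
2007-01-03,1,1,55
2007-01-04,0,0,8
2007-01-04,0,1,48
2007-01-04,1,0,8
2007-01-04,1,1,58
2007-01-05,0,0,8
2007-01-05,0,1,48
2007-01-05,1,0,8
2007-01-05,1,1,58
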