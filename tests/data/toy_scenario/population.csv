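unit_id,births,total_population_millions
west,100.0,1.0
east,300.0,3.0
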