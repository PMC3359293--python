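season_start_year,total_turtles,turtles_represented,total_nests,nests_analyzed
2004,54,40,358,128
2005,124,71,772,172
2006,76,44,536,130
2007,81,65,507,158
2008,27,26,170,99
2009,41,37,258,127
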