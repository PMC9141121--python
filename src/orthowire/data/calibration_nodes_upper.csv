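y_mm,z_mm,K_sweep,k_y
0,0,0,0
10,10,0.236239074,0.236239
20.04,20,0.047418085,0.004741799
30.23,30,0.021269355,0.021268997
40.75,40,0.014176957,0.014176989
51.85,50,0.014092645,0.014093042
59,51.38,0.1038303,0.10383
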