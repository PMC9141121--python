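source,z_mm,F_N,x_mm,k
published load sweep z=10mm,10,0.1,0.4233,0.236239
published load sweep z=10mm,10,0.2,0.8466,0.236239
published load sweep z=10mm,10,0.3,1.2699,0.236239
published load sweep z=10mm,10,0.4,1.6932,0.236239
published load sweep z=10mm,10,0.5,2.1165,0.236239
published load sweep z=10mm,10,0.8,3.3864,0.236239
published load sweep z=10mm,10,0.9,3.8097,0.236239
published load sweep z=10mm,10,1,4.233,0.236239
published load sweep z=10mm,10,2,8.466,0.236239
published load sweep z=10mm,10,5,21.165,0.236239
published load sweep z=10mm,10,10,42.33,0.236239
published load sweep z=20mm,20,0.1,2.1089,0.047418
published load sweep z=20mm,20,0.2,4.2178,0.047418
published load sweep z=20mm,20,0.3,6.3267,0.047418
published load sweep z=20mm,20,0.4,8.4356,0.047418
published load sweep z=20mm,20,0.5,10.5445,0.047418
published load sweep z=20mm,20,0.6,12.6534,0.047418
published load sweep z=20mm,20,0.7,14.7623,0.047418
published load sweep z=20mm,20,0.8,16.8712,0.047418
published load sweep z=20mm,20,0.9,18.9801,0.047418
published load sweep z=20mm,20,1,21.089,0.047418
published load sweep z=20mm,20,2,42.178,0.047418
published load sweep z=20mm,20,3,63.267,0.047418
published load sweep z=20mm,20,4,84.356,0.047418
published load sweep z=20mm,20,5,105.445,0.047418
published load sweep z=20mm,20,10,210.89,0.047418
published load sweep z=51.38mm (wire middle),51.38,0.1,0.96311,0.10383
published load sweep z=51.38mm (wire middle),51.38,0.2,1.92622,0.10383
published load sweep z=51.38mm (wire middle),51.38,0.3,2.88933,0.10383
published load sweep z=51.38mm (wire middle),51.38,0.4,3.85244,0.10383
published load sweep z=51.38mm (wire middle),51.38,0.5,4.8156,0.103829
published load sweep z=51.38mm (wire middle),51.38,0.6,5.77872,0.103829
published load sweep z=51.38mm (wire middle),51.38,0.7,6.74184,0.103829
published load sweep z=51.38mm (wire middle),51.38,0.8,7.70496,0.103829
published load sweep z=51.38mm (wire middle),51.38,0.9,8.66808,0.103829
published load sweep z=51.38mm (wire middle),51.38,1,9.6311,0.10383
published load sweep z=51.38mm (wire middle),51.38,2,19.2622,0.10383
published load sweep z=51.38mm (wire middle),51.38,3,28.8933,0.10383
published load sweep z=51.38mm (wire middle),51.38,4,38.5244,0.10383
published load sweep z=51.38mm (wire middle),51.38,5,48.1555,0.10383
published load sweep z=51.38mm (wire middle),51.38,10,96.311,0.10383
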