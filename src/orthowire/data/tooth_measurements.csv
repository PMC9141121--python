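tooth,arch,y_mm,x_mm,F_published_N
4.6,lower,28.65,1.31,0.017648
4.5,lower,38.32,2.75,0.069992
4.3,lower,54.41,3.07,0.140214
4.2,lower,61.03,4.45,0.461278
4.1,lower,66.41,5.41,0.961619
3.6,lower,29.09,1.22,0.019191
3.5,lower,38.23,3.08,0.079447
3.4,lower,47.03,1.11,0.01033
3.3,lower,54.81,3.24,0.166461
3.2,lower,65.17,3.13,0.178164
3.1,lower,71.25,4.74,5.906798
1.6,upper,25.66,2.08,0.002101
1.5,upper,35.71,4.56,0.146577
1.3,upper,52.63,9.2,0.207517
1.2,upper,63.43,8.15,0.384285
1.1,upper,73.11,5.84,11.8842
2.6,upper,25.66,1.6,0.001616
2.5,upper,34.83,2.29,0.074832
2.4,upper,43.06,4.28,0.009652
2.3,upper,51.51,2.62,0.028262
2.2,upper,61.49,4.81,0.474462
2.1,upper,70.36,4.65,4.449571
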