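surface,speed,mean_dbar,sd_dbar,min_di,max_di,impulse_rate_per_min,impulse_scale
A,30,0.36,0.05,0.21,0.93,0,8
A,60,0.46,0.02,0.22,1.27,0,8
A,90,0.58,0.04,0.35,1.43,0,8
A,120,0.74,0.05,0.43,1.82,0,8
A,150,0.95,0.10,0.51,2.27,0,8
B,30,0.97,0.26,0.29,3.07,2,8
B,60,0.80,0.07,0.30,3.36,2,8
B,90,0.78,0.05,0.41,1.72,2,8
B,120,0.86,0.06,0.55,1.93,2,8
C,30,3.60,0.18,0.63,6.61,0,8
C,60,4.44,0.09,1.74,7.76,0,8
D,30,2.14,0.21,0.64,4.50,6,8
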