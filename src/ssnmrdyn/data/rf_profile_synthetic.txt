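# synthetic rf-inhomogeneity profile (two-sided Gaussian, broader
# low-field tail typical of solenoid coils); NOT a measured nutation
# spectrum -- stand-in for probe characterisation data.
# columns: rf_field_hz  weight
88000	0.000000
89000	0.003318
90000	0.006396
91000	0.011582
92000	0.019702
93000	0.031483
94000	0.047262
95000	0.066650
96000	0.088297
97000	0.109887
98000	0.128471
99000	0.141098
100000	0.145577
101000	0.116569
102000	0.059848
103000	0.019702
104000	0.004158
105000	0.000000
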