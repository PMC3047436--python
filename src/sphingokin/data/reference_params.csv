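name,value,sem
kf1,1.30E+01,1.01E-02
kf2,5.62E-02,1.30E-02
kf3,1.11E-03,3.20E-03
kf4,1.49E-04,1.11E-03
kf5,1.61E-02,8.38E-04
kf6,5.28E-01,1.83E-02
kf7,1.81E-02,2.71E-03
kf8,2.99E-01,3.25E-02
kf9,1.15E-01,6.85E-03
kb9,1.7176,5.47E-03
kf10,3.88E-01,1.02E-02
kb10,8.63E-01,1.23E-02
kf11,1.07E-01,5.62E-03
kf12,2.49E-02,3.01E-03
kf13,5.00E-05,7.20E-06
kf14,8.25E-02,6.57E-03
kf15,9.07E-03,9.56E-03
kf16,8.03E-01,1.39E-02
kf17,1.29E-04,7.64E-06
kf18,1.12E-01,4.05E-03
kf19,6.50E-02,3.13E-02
kb19,4.72E-02,8.67E-03
kf20,4.48E-01,2.50E-02
kb20,1.3343,2.52E-02
kf21,1.91E-05,1.98E-02
kf22,9.79E-03,1.28E-03
kf23,0.00E+00,2.55E-03
kf24,2.39E-02,3.05E-03
kf25,4.58E-03,3.43E-03
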