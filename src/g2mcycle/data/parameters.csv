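symbol,value
k_s1,0.03093438
k_s5,0.0012
k_s8,0.0976875
k_s9,0.0325625
k_s12,0.04341667
k_s13,0.04341667
k_s15,0.0325625
k_s17,0.03798958
k_s20,0.0325625
k_s24,0.0325625
k_s27,0.00095517
k_s28,0.01218923
k_s31,0.00217083
k_s32,0.00542708
k_s33,0.10854167
k_s31.1,0.63502302
k_s32.1,0.9276405
k_f1,108.54166667
k_f2,119.94755063
k_f2.1,0.54270833
k_r2,22.72764813
k_f3,0.47411
k_r3,0.01085417
k_f4,12.45938937
k_f4.1,10.85416667
k_r4,4.41297854
k_r4.1,0.05427083
k_f5,1.08541667
k_r5,14.0
k'_f6,21.70833333
k_r6,0.325625
k_f7,8.62222438
k_r7,1.08541667
k_f8,0.10854167
k_f8.1,26.0
k_r8,43.41666667
k_r8.1,0.10854167
k_f9,0.325625
k_r9,2.17083333
k_f10,108.54166667
k_r10,0.54270833
k_f11,0.54270833
k_r11,21.70833333
k_f12,108.54166667
k_r12,0.21708333
k_f13,21.70833333
k_r13,10.85416667
k_r13.1,0.10854167
k_f14,21.70833333
k_f15,54.27083333
k_r15,0.10854167
k_f16,0.14324244
k_r16,0.04114815
k_f17,0.325625
k_r17,0.54270833
k_f18,13.025
k'_r18,0.21708333
k_d1.1,0.00217083
k_d1.2,0.325625
k_d1.3,0.3894475
k_d2.1,0.00217083
k_d2.2,0.65125
k_d2.3,0.05427083
k_d3.1,0.00217083
k_d3.2,0.325625
k_d3.3,0.02225104
k_d5,0.12
k_d6,0.05427083
k_d7.1,0.976875
k_d7.3,0.08683333
k_d8.1,0.10854167
k_d8.3,0.10854167
k_d9,0.10854167
k_d10.1,0.10854167
k_d10.2,0.75979167
k_d11.1,0.05427083
k_d11.3,0.62400604
k_d12.1,0.10854167
k_d12.3,0.325625
k_d13,0.10854167
k_d14,0.10854167
k_d15,0.10854167
k_d16.1,0.10854167
k_d16.3,0.21708333
k_d17.1,0.21708333
k_d17.2,0.10854167
k_d17.3,2.17083333
k_d18.1,0.325625
k_d18.3,1.08541667
k_d19.1,0.10854167
k_d19.3,1.08541667
k_d20,0.10854167
k_d21,0.10854167
k_d22,0.10854167
k_d23,0.05427083
k_d24.1,0.05427083
k_d24.2,0.54270833
k_d26.2,0.54270833
k_d27,0.04671633
k_d27.1,12.53174325
k_d28,0.05427083
k_d28.1,15.4084339
k_d29,0.05427083
k_d29.1,10.33955977
k_d31,0.08782106
k_d31.1,2.90623569
k_d32,0.56304904
k_d33,0.10854167
K_p53,0.0015
K_A1,0.28
K_A2,8.0
K_A3,0.02689
K_Cdc25P1,0.02
K_Cdc25P2,0.05
K_Cdc25,0.1
K_Plk1,0.1
K_Plk1P1,0.05
K_Plk1P2,0.1
K_Cdc20,0.1
K_Cdc20P1,0.05
K_Cdc20P2,0.1
K_Wip1,0.12195
K_MCD,0.05
K_DDS,12.0
K_CycB1,0.05
K_CycB2,0.05
K_MPF1,0.05
K_MPF2,0.05
K_preMPF,0.05
K_Pttg1,0.1
K_Sep,0.1
K_Wee1,0.1
eps,2.0
dds_gain,200.0
dds_act,0.36
dds_arrest,0.6
dds_decay,1e-08
tau,1.65
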