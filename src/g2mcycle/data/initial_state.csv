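species,value
CyclinB,0.00044663689099774605
MPF,0.02071546690735794
preMPF,0.3590265472552991
CDK1,0.6164324328643832
p21,0.16816518728990693
p21:MPF,0.0038255529729521627
Cdc25P,0.04911109145691223
Cdc25,0.14826770552929885
Wee1,0.1711835892962746
Wee1P,0.02676337548214803
Plk1P,0.002933232367550645
Plk1,0.05517783980752825
PP2A,0.3477822469022526
PP2AP,0.052217771523850355
APC/C,0.07665636417318358
APC/CP,0.0003935933967424786
Cdc20,0.0054846257073757785
Cdc20P,0.001437308205626235
APC/CP:Cdc20,7.712505976092786e-05
Cdh1,0.05487744528490737
Cdh1P,0.03992164999549801
APC/CT,0.03717629591681152
APC/CT:Cdh1,0.3007088696323338
Pttg1,0.2294312022065008
Separase,0.0026132305487311398
Pttg1:Separase,0.2973867694512693
ATM/ATR,0.017252213184670327
p53,0.023089065192521442
p53P,0.006012492698988382
p53P:Plk1P,1.9984888234785606e-05
Mdm2,0.04401444139989939
Wip1,0.019595393582250778
Mad2,1.0567696077555795
Mad2:Cdc20P,0.022410748711253935
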