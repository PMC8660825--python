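total_name,member_species,stoichiometry
CDK1_total,CDK1,1
CDK1_total,MPF,1
CDK1_total,preMPF,1
CDK1_total,p21:MPF,1
Separase_total,Separase,1
Separase_total,Pttg1:Separase,1
CyclinB_total,CyclinB,1
CyclinB_total,MPF,1
CyclinB_total,preMPF,1
CyclinB_total,p21:MPF,1
p21_total,p21,1
p21_total,p21:MPF,3
Cdc25_total,Cdc25,1
Cdc25_total,Cdc25P,1
Wee1_total,Wee1,1
Wee1_total,Wee1P,1
Plk1_total,Plk1,1
Plk1_total,Plk1P,1
Plk1_total,p53P:Plk1P,1
PP2A_total,PP2A,1
PP2A_total,PP2AP,1
APC/C_total,APC/C,1
APC/C_total,APC/CP,1
APC/C_total,APC/CP:Cdc20,1
APC/C_total,APC/CT,1
APC/C_total,APC/CT:Cdh1,1
Cdc20_total,Cdc20,1
Cdc20_total,Cdc20P,1
Cdc20_total,APC/CP:Cdc20,1
Cdc20_total,Mad2:Cdc20P,1
Cdh1_total,Cdh1,1
Cdh1_total,Cdh1P,1
Cdh1_total,APC/CT:Cdh1,1
Pttg1_total,Pttg1,1
Pttg1_total,Pttg1:Separase,1
p53_total,p53,1
p53_total,p53P,1
p53_total,p53P:Plk1P,1
Mad2_total,Mad2,1
Mad2_total,Mad2:Cdc20P,1
Mdm2_total,Mdm2,1
Wip1_total,Wip1,1
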