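row,label,genes,expected_p53wt,expected_p53null,expected_p53wt_depleted,expected_p53null_depleted
1,cyclinB-null,CCNB,inviable,inviable,inviable,inviable
2,p21-null,CDKN1A,viable:1.0,viable:1.0,viable:1.3,viable:1.9
3,cdc25-null,CDC25,inviable,inviable,inviable,inviable
4,wee1-null,WEE1,inviable,inviable,inviable,inviable
5,plk1-null,PLK1,inviable,inviable,inviable,inviable
6,pp2a-null,PP2A,inviable,inviable,inviable,inviable
7,apc-null,ANAPC1,inviable,inviable,inviable,inviable
8,cdc20-null,CDC20,inviable,inviable,inviable,inviable
9,cdh1-null,CDH1,viable:0.3,viable:0.3,viable:0.3,inviable
10,pttg1-null,PTTG1,viable:1.1,viable:1.1,viable:1.6,viable:2.1
11,atm-null,ATM/ATR,viable:1.0,viable:1.0,viable:1.4,viable:1.4
12,p53-null,TP53,viable:1.0,viable:1.0,viable:1.8,viable:1.8
13,mad2-null,MAD2L1,viable:1.0,viable:1.0,viable:1.4,viable:1.8
14,cdh1-null p21-null,CDH1;CDKN1A,inviable,inviable,inviable,inviable
15,p21-null pp2a-null,CDKN1A;PP2A,inviable,inviable,inviable,inviable
16,p21-null wee1-null,CDKN1A;WEE1,inviable,inviable,inviable,inviable
17,p21-null pttg1-null,CDKN1A;PTTG1,viable:1.1,viable:1.1,viable:1.6,viable:2.2
18,cdh1-null mad2-null,CDH1;MAD2L1,inviable,inviable,viable:0.3,viable:0.3
19,cdc20-null pttg1-null,CDC20;PTTG1,inviable,inviable,inviable,inviable
20,cdc20-null mad2-null,CDC20;MAD2L1,inviable,inviable,inviable,inviable
21,pp2a-null mad2-null,PP2A;MAD2L1,inviable,inviable,inviable,inviable
22,pp2a-null pttg1-null,PP2A;PTTG1,inviable,inviable,inviable,inviable
23,cdc25-null wee1-null,CDC25;WEE1,inviable,inviable,inviable,inviable
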