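compound_id,scaffold_id,r1_name,ki_nM,comfa_split,comfarf_split,comsia_split
1,I,Phenyl,420,test,train,test
2,I,Pyridyl,43,validation,validation,train
3,I,Tolyl,176,validation,validation,validation
4,I,Bromophenyl,117,test,test,test
5,I,Cyanophenyl,122,train,train,train
6,I,4-Methoxyphenyl,136,train,train,train
7,I,3-Methoxyphenyl,237,validation,validation,validation
8,I,2-Methoxyphenyl,153,test,test,test
9,I,1-Naphthalenyl,46,test,test,test
10,I,2-Naphthalenyl,9.6,test,train,train
11,I,6-Methoxy-2-naphthalenyl,264,train,train,train
12,I,Biphenyl,8.9,train,train,test
13,II,Phenyl,381,validation,validation,validation
14,V,Phenyl,38,train,train,train
15,V,2-Naphthalenyl,36,train,train,train
16,V,6-Methoxy-2-naphthalenyl,31,train,train,train
17,III,2-Naphthalenyl,9.1,train,train,train
18,IV,Phenyl,181,test,test,test
19,IV,2-Naphthalenyl,490,train,train,train
20,IV,6-Methoxy-2-naphthalenyl,782,train,train,train
21,VI,Phenyl,21,validation,validation,validation
22,VI,Tolyl,5.6,train,train,train
23,VI,4-Methoxyphenyl,34,train,train,train
24,VI,4-Bromophenyl,10.1,test,test,test
25,VI,4-Chlorophenyl,4.5,train,train,train
26,VI,4-Fluorophenyl,4,train,train,train
27,VI,4-Nitrophenyl,361,test,train,train
28,VI,Thienyl,9.5,train,train,train
29,VII,Phenyl,240,test,test,test
30,VII,Tolyl,321,test,test,test
31,VII,4-Methoxyphenyl,325,train,train,train
32,VII,4-Bromophenyl,560,train,train,train
33,VII,4-Chlorophenyl,579,train,train,train
34,VII,4-Fluorophenyl,312,train,train,train
35,VII,4-Nitrophenyl,681,train,train,train
36,VIII,Phenyl,9.3,train,train,train
37,VIII,Tolyl,9.2,train,train,train
38,VIII,4-Methoxyphenyl,185,train,train,train
39,VIII,4-Bromophenyl,244,train,train,train
40,VIII,4-Chlorophenyl,178,train,train,train
41,VIII,4-Fluorophenyl,64,train,train,train
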