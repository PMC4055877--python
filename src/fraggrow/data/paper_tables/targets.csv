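target,pdb_id,n_sites,n_active,n_compounds_A,rank_A,n_compounds_B,rank_B,n_compounds_C,rank_C
Akt,2UZT,17,3,1311,2,647,2,425,2
Bcl-XL,1YS1,10,1,726,1,373,2,245,2
CDK2,1VYZ,12,8,859,1,419,1,274,1
DNHA,2NM2,8,1,618,63,302,12,196,12
ERK2,2OJG,17,8,1159,1,583,1,386,1
HSP90,1BYQ,10,3,695,1,344,3,225,3
IMPDH,1NF7,7,3,469,1,230,1,150,1
Janus kinase,3JY9,10,1,777,28,380,17,248,17
KDR,1T46,10,3,757,1,379,1,249,1
Lactate dehydrogenase,1ARZ,10,1,701,1,344,9,225,9
MetAP2,1YW7,16,2,1273,36,627,10,407,10
MMP12,1Y93,6,3,392,1,192,1,125,1
NADP,2F10,13,6,839,1,404,3,256,3
PDE4,1MKD,14,1,1094,134,534,33,350,33
Urokinase,1ETF,11,1,727,43,338,31,209,28
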