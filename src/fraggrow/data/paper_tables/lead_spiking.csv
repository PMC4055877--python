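target,pdb_id,n_compounds,n_true_leads,best_lead_rank
Akt,2UZT,1361,50,41
Bcl-XL,1YS1,727,1,1
CDK2,1VYZ,900,41,1
DNHA,2NM2,634,16,1
ERK2,2OJG,1192,33,334
HSP90,1BYQ,699,4,1
IMPDH,1NF7,497,28,1
JanusKinase,3JY9,778,1,343
KDR,1T46,805,48,1
Lactatedehydrogenase,1ARZ,704,3,1
MetAP2,1YW7,1381,108,1
MMP12,1Y93,393,1,8
NADP,2F10,867,28,298
PDE4,1MKD,1102,8,303
Urokinase,1ETF,754,27,1
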