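target,pdb_ids,rank
Bcl-XL,1YS1;1YSG;1YSN;1YSW;2YXJ,1
ERK2,2OJG;2OJI;2OJJ;2OK1,1
LFA-1,1XDD;1XDG,1
MetAP2,1YW7;1YW8,58
NADP,2F10;3JSX,1
PDE4,1MKD;1Q9M,28
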