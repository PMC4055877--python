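# Side-chain scaffold file: base hydrocarbon compounds 1-9 and their
# derivatives, with one marked R position ("*") per row.
# This is a curated reconstruction: the published figure defining the nine
# base compounds is not machine-readable, so the rows below are small
# hydrocarbons chosen so that the stated per-set generation rules yield
# libraries of exactly 78 (A), 38 (B) and 25 (C) templates.  Replace this
# file to use a different scaffold inventory.
# Columns: smiles	name	scaffold_id	variant_id	tier
# tier = smallest set that uses this R position (C < B < A, nested).
# Rows with scaffold_id 8 (benzene family) or 9 (naphthalene family)
# additionally receive the per-set linker variants.
*C	methyl	1	1	C
*CC	ethyl	2	1	C
*CCC	propyl	3	1	C
*C(C)C	isopropyl	3	2	C
*CCCC	butyl	4	1	C
*CC(C)C	isobutyl	4	2	C
*C(C)CC	sec-butyl	4	3	C
*C(C)(C)C	tert-butyl	4	4	C
*CCCCC	pentyl	5	1	C
*CCC(C)C	isopentyl	5	2	C
*CC(C)(C)C	neopentyl	5	3	C
*C1CC1	cyclopropyl	6	1	C
*C1CCC1	cyclobutyl	6	2	C
*C1CCCC1	cyclopentyl	6	3	C
*C1CCCCC1	cyclohexyl	7	1	C
*CC1CC1	cyclopropylmethyl	6	4	C
*CC1CCCC1	cyclopentylmethyl	6	5	C
*CC1CCCCC1	cyclohexylmethyl	7	2	C
*CCC1CCCCC1	2-cyclohexylethyl	7	3	C
*C(C)(C)CC	tert-pentyl	5	4	B
*C(CC)CC	pentan-3-yl	5	5	B
*C(C)CCC	pentan-2-yl	5	6	B
*CC1CCC1	cyclobutylmethyl	6	6	B
*CCCCCC	hexyl	5	7	A
*CCC(C)CC	3-methylpentyl	5	8	A
*CC(CC)CC	2-ethylbutyl	5	9	A
*CCC(C)(C)C	3,3-dimethylbutyl	5	10	A
*C1(C)CCCCC1	1-methylcyclohexyl	7	4	A
*C1CCCCCC1	cycloheptyl	7	5	A
*C1CCC(C)(C)CC1	4,4-dimethylcyclohexyl	7	6	A
*c1ccccc1	phenyl	8	1	C
*c1cccc2ccccc12	naphthalen-1-yl	9	1	C
*c1ccc2ccccc2c1	naphthalen-2-yl	9	2	C
*c1ccc(C)cc1	4-methylphenyl	8	2	B
*c1ccccc1C	2-methylphenyl	8	3	B
*c1cccc(C)c1	3-methylphenyl	8	4	A
*c1cc(C)ccc1C	2,5-dimethylphenyl	8	5	A
*c1cccc(C)c1C	2,3-dimethylphenyl	8	6	A
*c1ccc(C)c(C)c1	3,4-dimethylphenyl	8	7	A
*c1ccc(-c2ccccc2)cc1	biphenyl-4-yl	8	8	A
*c1cccc(-c2ccccc2)c1	biphenyl-3-yl	8	9	A
*c1ccc(C)c2ccccc12	4-methylnaphthalen-1-yl	9	3	A
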