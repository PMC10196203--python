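# Star-allele / HLA-allele function assignments (synthetic curated snapshot).
# activity_value populated only for genes with uses_activity_score=true; copy-number
# alleles (*1x2) carry the multiplied value. CFTR risk alleles mark the genotype that
# predicts non-response to the targeted drug (synthetic simplification).
gene_symbol	allele	function_class	activity_value
CYP2D6	*1	normal	1
CYP2D6	*2	normal	1
CYP2D6	*4	no_function	0
CYP2D6	*5	no_function	0
CYP2D6	*6	no_function	0
CYP2D6	*10	decreased	0.25
CYP2D6	*17	decreased	0.5
CYP2D6	*41	decreased	0.5
CYP2D6	*1x2	normal	2
CYP2D6	*2x2	normal	2
CYP2C9	*1	normal	1
CYP2C9	*2	decreased	0.5
CYP2C9	*3	no_function	0
CYP2C19	*1	normal
CYP2C19	*2	no_function
CYP2C19	*3	no_function
CYP2C19	*9	decreased
CYP2C19	*17	increased
TPMT	*1	normal
TPMT	*2	no_function
TPMT	*3A	no_function
TPMT	*3B	no_function
TPMT	*3C	no_function
NUDT15	*1	normal
NUDT15	*2	no_function
NUDT15	*3	no_function
SLCO1B1	*1	normal
SLCO1B1	*5	no_function
SLCO1B1	*15	no_function
HLA-B	B*57:01	risk
HLA-B	B*58:01	risk
HLA-B	B*15:02	risk
HLA-B	B*07:02	non_risk
CFTR	F508del	risk
CFTR	G551D	non_risk
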