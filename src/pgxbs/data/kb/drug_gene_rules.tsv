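# Drug–gene rules (synthetic curated snapshot of CPIC-level evidence assignments).
# gene_role: activating = enzyme converts prodrug to active moiety; inactivating = enzyme
# clears the active drug; target = response biomarker; immune_risk = HLA-type SCAR risk.
# risk_alleles restricts carrier calls to the drug-specific allele(s); empty = any risk allele.
drug_name	gene_symbol	cpic_level	gene_role	risk_alleles
codeine	CYP2D6	A	activating
tramadol	CYP2D6	A	activating
clomipramine	CYP2D6	A	inactivating
clomipramine	CYP2C19	A	inactivating
amitriptyline	CYP2D6	A	inactivating
amitriptyline	CYP2C19	A	inactivating
clopidogrel	CYP2C19	A	activating
warfarin	CYP2C9	A	inactivating
azathioprine	TPMT	A	inactivating
azathioprine	NUDT15	A	inactivating
allopurinol	HLA-B	A	immune_risk	B*58:01
abacavir	HLA-B	A	immune_risk	B*57:01
carbamazepine	HLA-B	A	immune_risk	B*15:02
simvastatin	SLCO1B1	A	inactivating
ivacaftor	CFTR	A	target
risperidone	CYP2D6	B	inactivating
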