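# Perpetrator-drug → enzyme interaction strengths used for phenoconversion.
perpetrator_drug	gene_symbol	strength
paroxetine	CYP2D6	strong_inhibitor
fluoxetine	CYP2D6	strong_inhibitor
bupropion	CYP2D6	strong_inhibitor
terbinafine	CYP2D6	strong_inhibitor
duloxetine	CYP2D6	moderate_inhibitor
fluvoxamine	CYP2C19	strong_inhibitor
fluconazole	CYP2C19	moderate_inhibitor
esomeprazole	CYP2C19	moderate_inhibitor
rifampicin	CYP2C19	strong_inducer
rifampicin	CYP2C9	strong_inducer
carbamazepine	CYP2C9	moderate_inducer
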