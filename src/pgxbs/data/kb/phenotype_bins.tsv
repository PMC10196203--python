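# Activity-score → metabolizer-phenotype bins for genes with uses_activity_score=true.
# Bounds are inclusive and partition the attainable activity-score lattice
# (allele values are multiples of 0.25, so gaps between bins are never attainable).
gene_symbol	phenotype_label	lower_bound	upper_bound
CYP2D6	PM	0	0
CYP2D6	IM	0.25	1
CYP2D6	NM	1.25	2.25
CYP2D6	UM	2.5	6
CYP2C9	PM	0	0.5
CYP2C9	IM	0.75	1.5
CYP2C9	NM	1.75	2
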