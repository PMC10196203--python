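# Curated pharmacogene definitions (synthetic snapshot for the shipped knowledge base).
# category: exposure = pharmacokinetic gene, response = drug-target gene, safety = HLA-type immune risk.
# phenotype_system: metabolizer (PM/IM/NM/RM/UM) or carrier (positive/negative).
gene_symbol	category	phenotype_system	uses_activity_score
CYP2D6	exposure	metabolizer	true
CYP2C19	exposure	metabolizer	false
CYP2C9	exposure	metabolizer	true
TPMT	exposure	metabolizer	false
NUDT15	exposure	metabolizer	false
SLCO1B1	exposure	metabolizer	false
HLA-B	safety	carrier	false
CFTR	response	carrier	false
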