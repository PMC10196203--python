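# gene	diplotype
CYP2D6	*1/*1x2
CYP2C19	*1/*1
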