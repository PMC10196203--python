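# Activity-score multipliers applied per matching perpetrator (editable data, not code).
strength	multiplier
strong_inhibitor	0.0
moderate_inhibitor	0.5
strong_inducer	2.0
moderate_inducer	1.5
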