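pgxbs-kb 0.1.0 (synthetic curated snapshot, 2023-era evidence levels; not a live CPIC export)
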