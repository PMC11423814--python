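substrate_stiffness: 1.0e7
label: glass
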