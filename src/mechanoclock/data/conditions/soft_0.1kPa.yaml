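substrate_stiffness: 0.1
label: soft_0.1kPa
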