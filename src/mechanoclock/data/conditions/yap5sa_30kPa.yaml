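substrate_stiffness: 30.0
mutation: YAP_5SA
label: yap5sa_30kPa
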