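label,substrate_stiffness,y27632,cytochalasin_d,latrunculin,jasplakinolide,T_mean,T_sd,A_mean,A_sd
stiffness_0.1kPa,0.1,0,0,0,0,24.0,0.7,2.1,0.35
stiffness_1kPa,1.0,0,0,0,0,23.9,0.6,2.0,0.30
stiffness_4kPa,4.0,0,0,0,0,23.8,0.6,1.65,0.28
stiffness_12.8kPa,12.8,0,0,0,0,23.7,0.5,1.35,0.25
control_glass,1.0e7,0,0,0,0,23.5,0.5,1.0,0.15
y27632_2.5uM,1.0e7,2.5,0,0,0,23.9,0.7,2.0,0.35
y27632_10uM,1.0e7,10.0,0,0,0,24.0,0.8,2.1,0.40
cytochalasinD_0.25uM,1.0e7,0,0.25,0,0,23.8,0.7,1.6,0.30
cytochalasinD_1uM,1.0e7,0,1.0,0,0,23.8,0.8,1.7,0.35
latrunculinB_0.1uM,1.0e7,0,0,0.1,0,23.7,0.7,1.45,0.30
jasplakinolide_0.5uM,1.0e7,0,0,0,0.5,23.6,0.9,0.55,0.20
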