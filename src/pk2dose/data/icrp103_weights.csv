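target,w_T
red_bone_marrow,0.12
colon,0.12
lung,0.12
stomach,0.12
breast,0.12
remainder,0.12
gonads,0.08
bladder,0.04
oesophagus,0.04
liver,0.04
thyroid,0.04
bone_surface,0.01
brain,0.01
salivary_glands,0.01
skin,0.01
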