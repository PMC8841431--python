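species,region,mass_kg
human_adult_male,whole_body,73.0
human_adult_male,heart,0.33
human_adult_male,lung,1.2
human_adult_male,kidney,0.31
human_adult_male,liver,1.8
human_adult_male,bone,10.5
mouse_c57bl6,whole_body,0.025
mouse_c57bl6,heart,0.00015
mouse_c57bl6,lung,0.00015
mouse_c57bl6,kidney,0.0003
mouse_c57bl6,liver,0.0013
mouse_c57bl6,bone,0.0025
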