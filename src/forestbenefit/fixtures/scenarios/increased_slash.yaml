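# Slash extraction raised 2.3x to the recommended maximum (0.18 t DM/ha/yr).
name: increased_slash
harvest_target_fraction: 0.95
rotation_delta: 0.0
set_aside_fraction: 0.103
fertilized_area: 2100.0
slash_extraction: 0.18
stump_extraction: 0.0
contorta_area: 0.0
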