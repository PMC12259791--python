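# Rotation period prolonged by 30 years.
name: longer_rotation
harvest_target_fraction: 0.95
rotation_delta: 30.0
set_aside_fraction: 0.103
fertilized_area: 2100.0
slash_extraction: 0.078
stump_extraction: 0.0
contorta_area: 0.0
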