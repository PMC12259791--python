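# High-fertilisation replication: fertilised area increased 35x over BAU
# (the level actually used in the study being replicated).
name: petersson_fertilization_35x
harvest_target_fraction: 0.95
rotation_delta: 0.0
set_aside_fraction: 0.103
fertilized_area: 73500.0
slash_extraction: 0.078
stump_extraction: 0.0
contorta_area: 0.0
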