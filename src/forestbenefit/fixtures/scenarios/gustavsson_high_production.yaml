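# High-production replication: doubled fertilisation, heavy slash and stump
# extraction and fast-growing species planting.
name: gustavsson_high_production
harvest_target_fraction: 0.95
rotation_delta: 0.0
set_aside_fraction: 0.103
fertilized_area: 4200.0
slash_extraction: 0.43
stump_extraction: 0.23
contorta_area: 5359.0
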