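# Acceptable maximum intervention levels (Swedish Forest Agency / Skogforsk).
set_aside_fraction: 0.309
fertilized_area: 6300.0        # ha/yr (3x the current fertilised area)
slash_extraction: 0.18         # t DM/ha/yr (21 TWh equivalent, 2.3x present)
stump_extraction: 0.013        # t DM/ha/yr (5-10% of harvested area)
contorta_area: 1504.0          # ha/yr (Forestry Act maximum, scaled to county)
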