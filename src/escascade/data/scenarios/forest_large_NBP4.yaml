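# Stylized Nordic Bioeconomy Pathway scenario for the packaged
# synthetic archetype catchment. NOT a transcription of the study's
# supplementary land-use tables: hectare deltas here are generated
# from the pathway narratives by escascade.synthetic.
scenario_id: NBP4
land_cover_change:
  deltas_ha:
    cropland: -819.1139471474042
    grassland: -319.63847865067856
    built_up: 1138.7524257980829
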