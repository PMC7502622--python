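# Stylized Nordic Bioeconomy Pathway scenario for the packaged
# synthetic archetype catchment. NOT a transcription of the study's
# supplementary land-use tables: hectare deltas here are generated
# from the pathway narratives by escascade.synthetic.
scenario_id: NBP2
land_cover_change:
  deltas_ha:
    cropland: -7.717750692806049
    grassland: 7.717750692806049
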