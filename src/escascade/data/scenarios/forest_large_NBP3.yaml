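# Stylized Nordic Bioeconomy Pathway scenario for the packaged
# synthetic archetype catchment. NOT a transcription of the study's
# supplementary land-use tables: hectare deltas here are generated
# from the pathway narratives by escascade.synthetic.
scenario_id: NBP3
land_cover_change:
  deltas_ha:
    grassland: -1703.0180839072536
    wetland: -2768.3976062623087
    deciduous_forest: -4800.0990429493195
    cropland: 5562.908839871329
    coniferous_forest: 3708.605893247553
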