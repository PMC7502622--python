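# Stylized Nordic Bioeconomy Pathway scenario for the packaged
# synthetic archetype catchment. NOT a transcription of the study's
# supplementary land-use tables: hectare deltas here are generated
# from the pathway narratives by escascade.synthetic.
scenario_id: NBP4
land_cover_change:
  deltas_ha:
    cropland: -18.943464870311146
    grassland: -1.1018182809255817
    built_up: 20.045283151236728
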