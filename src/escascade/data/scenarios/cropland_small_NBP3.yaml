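# Stylized Nordic Bioeconomy Pathway scenario for the packaged
# synthetic archetype catchment. NOT a transcription of the study's
# supplementary land-use tables: hectare deltas here are generated
# from the pathway narratives by escascade.synthetic.
scenario_id: NBP3
land_cover_change:
  deltas_ha:
    grassland: -6.499983477006604
    wetland: -4.976076869108283
    deciduous_forest: -1.1049102459644498
    cropland: 7.548582355247602
    coniferous_forest: 5.032388236831736
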