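# Stylized Nordic Bioeconomy Pathway scenario for the packaged
# synthetic archetype catchment. NOT a transcription of the study's
# supplementary land-use tables: hectare deltas here are generated
# from the pathway narratives by escascade.synthetic.
scenario_id: NBP5
land_cover_change:
  deltas_ha:
    grassland: -7.71740926661413
    wetland: -6.4342751513623435
    deciduous_forest: -1.4742967001885916
    riparian_woodland: -1.9199858378437296
    cropland: 9.650281825804838
    coniferous_forest: 7.895685130203957
river_metric_changes:
  riparian_fraction: 0.15690779299814553
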