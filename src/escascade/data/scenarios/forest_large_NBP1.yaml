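# Stylized Nordic Bioeconomy Pathway scenario for the packaged
# synthetic archetype catchment. NOT a transcription of the study's
# supplementary land-use tables: hectare deltas here are generated
# from the pathway narratives by escascade.synthetic.
scenario_id: NBP1
land_cover_change:
  deltas_ha:
    cropland: -3727.2274934873044
    coniferous_forest: -10222.859870132415
    grassland: 5580.034945447888
    riparian_woodland: 4185.026209085916
    wetland: 4185.026209085916
river_metric_changes:
  riparian_fraction: 0.7488716917764651
  shaded_fraction: 0.817
parameter_overrides:
  carbon_price: 20.0
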