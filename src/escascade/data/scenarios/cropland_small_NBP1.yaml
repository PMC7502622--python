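# Stylized Nordic Bioeconomy Pathway scenario for the packaged
# synthetic archetype catchment. NOT a transcription of the study's
# supplementary land-use tables: hectare deltas here are generated
# from the pathway narratives by escascade.synthetic.
scenario_id: NBP1
land_cover_change:
  deltas_ha:
    cropland: -75.9584476311008
    coniferous_forest: -0.6919691193206592
    grassland: 30.660166700168585
    riparian_woodland: 22.995125025126438
    wetland: 22.995125025126438
river_metric_changes:
  riparian_fraction: 0.45690779299814555
  shaded_fraction: 0.11900000000000001
parameter_overrides:
  carbon_price: 20.0
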