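# Stylized Nordic Bioeconomy Pathway scenario for the packaged
# synthetic archetype catchment. NOT a transcription of the study's
# supplementary land-use tables: hectare deltas here are generated
# from the pathway narratives by escascade.synthetic.
scenario_id: NBP5
land_cover_change:
  deltas_ha:
    grassland: -2545.498265271471
    wetland: -3438.1856998790445
    deciduous_forest: -6435.69425413888
    riparian_woodland: -3.9334288248519434e-05
    cropland: 6830.658042243027
    coniferous_forest: 5588.720216380659
river_metric_changes:
  riparian_fraction: 0.448871691776465
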