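catchment,field,value
cropland_small_42,land_cover.catchment_area,470
cropland_small_42,land_cover.cropland,360.0639014
cropland_small_42,land_cover.grassland,20.84383044
cropland_small_42,land_cover.coniferous_forest,5.837772075
cropland_small_42,land_cover.deciduous_forest,5.044678828
cropland_small_42,land_cover.riparian_woodland,8.844983345
cropland_small_42,land_cover.wetland,10.83126857
cropland_small_42,land_cover.built_up,31.8684208
cropland_small_42,land_cover.open_water,2.385418066
cropland_small_42,land_cover.other,24.27972645
cropland_small_42,river.main_river_length,5.772923935
cropland_small_42,river.shaded_fraction,0.019
cropland_small_42,river.riparian_fraction,0.256907793
cropland_small_42,river.floodplain_area,0
cropland_small_42,river.hydropower_generation,0
cropland_small_42,river.drinking_water_extraction,0
cropland_small_42,river.flood_p_sedimentation,0
cropland_small_42,river.corridor_share_built_up,0.02
cropland_small_42,river.corridor_share_agricultural,0.9
cropland_small_42,river.corridor_share_woodland,0.08
cropland_small_42,river.discharges_directly_to_sea,1
cropland_small_42,beneficiaries.households,438
cropland_small_42,beneficiaries.angler_household_fraction,0.1
cropland_small_42,beneficiaries.resident_visits_value_base,1102.08486
cropland_small_42,beneficiaries.tourist_visitors,2079
cropland_small_42,beneficiaries.wtp_angler,275
cropland_small_42,beneficiaries.wtp_resident,10
cropland_small_42,beneficiaries.wtp_tourist,20
cropland_small_42,beneficiaries.wtp_biodiversity_household,5
cropland_small_42,beneficiaries.conservation_household_fraction,0.4418103873
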