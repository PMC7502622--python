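catchment,field,value
forest_large_7,land_cover.catchment_area,150000
forest_large_7,land_cover.cropland,18181.25886
forest_large_7,land_cover.grassland,6006.855063
forest_large_7,land_cover.coniferous_forest,78920.81179
forest_large_7,land_cover.deciduous_forest,22332.05221
forest_large_7,land_cover.riparian_woodland,0.0002057910463
forest_large_7,land_cover.wetland,5767.295218
forest_large_7,land_cover.built_up,1472.194254
forest_large_7,land_cover.open_water,14639.21859
forest_large_7,land_cover.other,2680.313816
forest_large_7,river.main_river_length,149.6850198
forest_large_7,river.shaded_fraction,0.717
forest_large_7,river.riparian_fraction,0.5488716918
forest_large_7,river.floodplain_area,396.6880443
forest_large_7,river.hydropower_generation,9000000
forest_large_7,river.drinking_water_extraction,2700
forest_large_7,river.flood_p_sedimentation,500
forest_large_7,river.corridor_share_built_up,0.05
forest_large_7,river.corridor_share_agricultural,0.45
forest_large_7,river.corridor_share_woodland,0.5
forest_large_7,river.discharges_directly_to_sea,0
forest_large_7,beneficiaries.households,13729
forest_large_7,beneficiaries.angler_household_fraction,0.1
forest_large_7,beneficiaries.resident_visits_value_base,15928.55101
forest_large_7,beneficiaries.tourist_visitors,18612
forest_large_7,beneficiaries.wtp_angler,275
forest_large_7,beneficiaries.wtp_resident,10
forest_large_7,beneficiaries.wtp_tourist,20
forest_large_7,beneficiaries.wtp_biodiversity_household,5
forest_large_7,beneficiaries.conservation_household_fraction,0.5450158417
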