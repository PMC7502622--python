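crop_revenue: 400.0
dairy_revenue: 500.0
timber_annuity: 200.0
wild_products_rate: 24.0
game_share: 0.8
electricity_price: 0.05
water_price: 0.5
c_seq_coniferous: 6.0
c_seq_deciduous: 5.0
c_seq_riparian: 4.0
carbon_price: 5.0
p_price: 1.1322
erodible_p_grassland: 1.0
erodible_p_cropland: 2.0
flood_damage_built: 252.0
flood_damage_agri: 7.0
flood_damage_wood: 1.0
flood_depth_factor: 0.2
flood_annualization: 0.01
instream_p_retention: 10.0
pest_woodland_threshold: 0.25
pest_reduced_productivity: 0.8
shade_threshold: 0.5
residual_trout_survival: 0.1
scenic_low_forest_threshold: 0.2
scenic_high_forest_threshold: 0.7
scenic_low_appreciation: 0.6
scenic_high_appreciation: 0.8
tev_relative_standard_error: 0.24
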