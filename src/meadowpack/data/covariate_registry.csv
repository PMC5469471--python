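name,label,category,ranked,use_in_cart,yose_only
ranked_mean_precip,Ranked Mean Precipitation,climate,1,1,0
ranked_sd_precip,Ranked Standard Deviation of Precipitation,climate,1,0,0
ranked_sd_avg_temp,Ranked Standard Deviation of Average Temperature,climate,1,0,0
elevation,Elevation,climate,0,1,0
short_hair_sedge_cover,Short Hair Sedge Cover (%),hydrologic,0,0,0
semi_perm_flooded_cover,Semi-permanent Flooded Meadow Cover (%),hydrologic,0,0,0
ranked_mean_melt_date,Ranked Mean Meadow Melt Date,hydrologic,1,0,0
ranked_sd_melt_date,Ranked Standard Deviation for Meadow Melt Date,hydrologic,1,0,0
ranked_sd_snow50_date,Ranked Standard Deviation for meadow 50% Snow Cover Date,hydrologic,1,0,0
ranked_mean_snow50_date,Ranked Mean Meadow 50% Snow Cover Date,hydrologic,1,1,0
ranked_mean_tc_greenness,Ranked Mean Tasseled Cap Greenness Index,hydrologic,1,1,0
ranked_sd_tc_greenness,Ranked Standard Deviation for Tasseled Cap Greenness Index,hydrologic,1,1,0
ranked_avg_sd_tc_greenness,Ranked Average of Standard Deviation for Tasseled Cap Greenness,hydrologic,1,0,0
ranked_mean_tc_wetness,Ranked Mean Tasseled Cap Wetness,hydrologic,1,1,0
ranked_sd_tc_wetness,Ranked Standard Deviation for Tasseled Cap Wetness,hydrologic,1,1,0
ranked_avg_sd_tc_wetness,Ranked Average of Standard Deviation for Tasseled Cap Wetness,hydrologic,1,0,0
ranked_ndvi,Ranked NDVI,hydrologic,1,1,0
ranked_sd_ndvi,Ranked Standard Deviation for NDVI,hydrologic,1,1,0
ranked_avg_sd_ndvi,Ranked Average of Standard Deviation for NDVI,hydrologic,1,0,0
dist_nearest_lake,Distance to Nearest Lake,accessibility,0,1,0
dist_nearest_meadow,Distance to Nearest Meadow,accessibility,0,1,0
dist_nearest_road,Distance to Nearest Road,accessibility,0,0,0
dist_nearest_trail,Distance to Nearest Trail,accessibility,0,1,0
travel_time_trailhead,Estimated Minimum Travel Time From Trailhead,accessibility,0,0,1
nearest_meadow_cum_elev_change,Nearest Meadow Cumulative Elevation Change,accessibility,0,1,0
nearest_meadow_max_slope,Nearest Meadow Maximum Slope,accessibility,0,0,0
meadow_area,Meadow Area,accessibility,0,1,0
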