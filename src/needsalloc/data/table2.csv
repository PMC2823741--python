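variable,group,description,mean,std_dev,factor_score
car_truck,,Car/Truck,0.009,0.093,0.068
radio,,Radio,0.934,0.248,0.016
cell_phone,,Cell phone,0.060,0.238,0.111
television,,Television,0.073,0.260,0.093
bicycle,,Bicycle,0.425,0.494,-0.007
refrigerator,,Refrigerator,0.018,0.132,0.099
cattle,,Cattle,0.476,0.499,0.040
goat,,Goat,0.654,0.476,0.024
water_piped_dwelling,water,"Piped into dwelling, household uses bottled water",0.014,0.119,0.084
water_piped_outside,water,Piped outside dwelling,0.033,0.179,0.071
water_public_tap,water,Public tap/standpipe,0.126,0.331,0.042
water_tubewell_borehole,water,"Tube well/borehole, tube well with powered pump, cart with small tank/drum",0.516,0.500,-0.052
water_unprotected,water,Unprotected well/spring,0.170,0.376,-0.032
water_surface_rain,water,"Surface water, rainwater collection",0.067,0.250,-0.016
toilet_flush,toilet,Flush toilet of any type,0.020,0.140,0.092
toilet_pit_slab,toilet,"Pit latrine with slab, pit latrine with slab and foot rest",0.101,0.301,0.037
toilet_pit_noslab,toilet,Pit latrine without slab/open pit,0.680,0.466,-0.055
toilet_pit_slab_cover,toilet,"Pit latrine with slab and cover, pit latrine with slab/cover and foot rest",0.036,0.187,0.017
toilet_none_composting,toilet,"No toilet, composting toilet, hanging toilet/latrine",0.138,0.344,-0.025
floor_finished,floor,"Tiles, cement, carpet, wood planks, other",0.167,0.373,0.133
floor_sand,floor,Sand,0.789,0.408,-0.128
roof_thatch,roof,"Thatch, sod, rustic mat, palm/bamboo",0.735,0.441,-0.124
roof_metal,roof,Metal,0.229,0.420,0.126
fuel_electricity_gas,fuel,"Electricity, all types of gas, kerosene",0.009,0.096,0.080
fuel_charcoal,fuel,"Charcoal, coal",0.047,0.213,0.094
fuel_wood,fuel,Wood,0.903,0.296,-0.116
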