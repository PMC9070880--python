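district_id,tland_flood,tland_sprinkler,tland_drip,twater,tlabor,withdraw_reach,return_reach
alto_aragon,137.5,115.5,0,1836,1339.25,428,406
bardenas,104.5,55,0,1080,753.5,421,264
jalon,26.4,11,66,864,2572.9,426,274
lodosa,38.5,0,27.5,2030.4,1633.5,433,406
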