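reach_id,downstream_id,length_km,local_inflow,loss,r_ir,r_urb,min_env_flow,min_env_flow_drought,closure_term,beta,wua_flow_scale,valuation_tier
202,264,181.49,2000,0,0.2,0.5,0,,0,-9.65,9.829637227e-05,high
264,274,120.994,300,150,0.2,0.5,300,,0,-2.07,0.0002280899506,low
274,406,151.242,300,150,0.2,0.5,0,,0,-1.42,0.00028644195,low
406,418,252.07,300,250,0.2,0.5,945,640,0,-16.39,2.019428402e-05,low
418,662,302.484,300,300,0.2,0.5,0,,0,-1.89,0.0001063952828,low
421,264,604.968,1200,0,0.2,0.5,0,,0,-0.12,0.06308865553,medium
426,274,453.726,900,0,0.2,0.5,0,,0,-0.52,0.02665950694,low
428,406,806.623,1800,0,0.2,0.5,0,,0,-0.3,0.04243218919,medium
433,406,907.451,2200,0,0.2,0.5,0,,0,-0.1,0.03762415014,medium
441,418,705.795,1700,0,0.2,0.5,0,,0,-8.14,0.000123919528,high
446,418,504.14,1300,0,0.2,0.5,0,,0,-1.96,0.0005942416533,medium
455,662,352.898,1100,0,0.2,0.5,0,,0,-9.61,0.0001522502992,high
463,662,403.312,900,0,0.2,0.5,0,,0,-0.23,0.006507602164,low
662,,120.994,300,350,0.2,0.5,3000,,0,-0.26,0.0004539378754,high
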