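district_id,crop_id,group,tech,price,cost,water_req,labor_req,observed_acreage,avg_yield
alto_aragon,corn,field,flood,180,1550,8.678389109,6,75,11
alto_aragon,corn,field,sprinkler,180,1710,6.557005105,6,60,11.5
alto_aragon,alfalfa,field,flood,150,1400,9.642654566,5,50,13.5
alto_aragon,barley,field,sprinkler,170,810,3.857061826,3.5,45,4.8
bardenas,wheat,field,flood,190,700,5.472636816,3.5,60,5.5
bardenas,corn,field,sprinkler,180,1710,6.467661692,6,50,11.2
bardenas,alfalfa,field,flood,150,1400,9.950248756,5,35,13
jalon,fruit,fruit,drip,450,7460,7.787610619,28,60,22
jalon,fruit,fruit,flood,450,7200,11.32743363,26,24,20
jalon,wheat,field,sprinkler,190,860,6.088495575,3.5,10,5.8
lodosa,vegetable,vegetable,drip,320,6260,20.7607362,35,25,28
lodosa,fruit,fruit,flood,450,7200,36.90797546,26,20,21
lodosa,corn,field,flood,180,1550,41.52147239,6,15,10.5
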