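{
  "description": "toy_ebro: fixed 14-reach basin fixture. Network topology, habitat coefficients (beta), valuation tiers and control-point minimum flows follow the published study-basin values; district and city economics are SYNTHETIC stand-ins (the study's calibration dataset is not public). Files are frozen; regenerate nothing at run time.",
  "files": {
    "toy_ebro_cities.csv": "1d049692b80ddf9abcf937cc4e260cb5d668d84d94bf2d2e2071dbfd0dbe91c2",
    "toy_ebro_districts.csv": "6617887295cd21bcaf48cd528daf88fba902d8c87d88c9faa51546d8fc0e361a",
    "toy_ebro_endowments.csv": "000cfc5f8ae95ed15bab40f0088bf4ee83dc9088710d25254ffaacded38de20e",
    "toy_ebro_network.csv": "05e34b44aa51c434c7c94a1281ee5877b99502ae2229bfa7325f3108f3686168"
  }
}
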