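city_id,a_d,b_d,a_s,b_s,withdraw_reach,return_reach
coastal,3.15,0.02,0.6,0.005,418,662
zaragoza,3,0.006,0.6,0.002,406,418
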