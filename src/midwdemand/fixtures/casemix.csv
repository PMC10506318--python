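drg,soi,age_band,share
560,1,25_34,0.60
560,1,35_39,0.20
540,1,25_34,0.15
540,1,35_39,0.05
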