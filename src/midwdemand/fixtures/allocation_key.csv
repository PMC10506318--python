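pillar,share_percent
prenatal,5.4
birth_prep,2.7
outpatient_postnatal,11.9
inpatient_postnatal,48.0
other,32.0
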