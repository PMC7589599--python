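demand_id,facility_id,distance_km
i1,j1,2.0
i1,j2,10.0
i1,j3,31.0
i2,j1,6.0
i2,j2,20.0
i2,j3,12.0
i3,j2,25.0
i3,j3,4.0
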