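id,region_id,county_id,population,x_km,y_km
i1,i1,CA,1000,0.0,0.0
i2,i2,CA,2000,5.0,2.0
i3,i3,CB,500,20.0,15.0
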