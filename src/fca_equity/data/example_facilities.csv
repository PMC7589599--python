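id,region_id,county_id,capacity,rating,x_km,y_km
j1,i1,CA,2.0,4.0,1.0,1.0
j2,i2,CA,3.0,3.0,8.0,4.0
j3,i3,CB,1.0,5.0,21.0,16.0
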