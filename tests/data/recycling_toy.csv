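sample_id,condition,timepoint,stain,median_fi,replicate
r1,activated,0,stained,100.0,1
r2,activated,5,stained,150.0,1
r3,activated,10,stained,120.0,1
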