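sample_id,condition,timepoint,stain,median_fi,replicate
s1,activated,30,stained,150.0,1
s2,activated,30,stained,170.0,2
s3,resting,30,stained,100.0,1
s4,resting,30,stained,110.0,2
s5,activated,30,unstained,10.0,1
s6,resting,30,unstained,5.0,1
s7,activated,0,stained,100.0,1
s8,resting,0,stained,100.0,1
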