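lane,target,actin
1,100.0,100.0
2,50.0,100.0
3,80.0,160.0
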