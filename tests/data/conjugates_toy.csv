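sample_id,singles_t,singles_b,conjugates,ctrl_singles_t,ctrl_singles_b,ctrl_conjugates
c1,4000,5000,500,4802,6000,98
c2,3000,3000,0,3000,3000,0
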