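head_state,non_contracted,near_head,middle,near_tip
dna_full,196,25,3,104
partial_dna,3,1,0,7
empty,12,1,0,12
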