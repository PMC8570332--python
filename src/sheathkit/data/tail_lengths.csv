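virus,extended_length_ang,contracted_length_ang
T4,925,420
phi812K1-420,2020,808
phage G,4500,2040
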