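state,outer_diameter_ang,inner_diameter_ang,tail_length_ang,twist_deg,rise_ang,n_start,handedness,point_group_order
non_contracted,240,60,4500,20.57,41.53,6,right,6
contracted,320,120,4500,27.13,18.89,6,right,6
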