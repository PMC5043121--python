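segment,mass_fraction,com_location_fraction
head_neck,0.081,0.500
trunk,0.497,0.500
upper_arm_r,0.028,0.436
upper_arm_l,0.028,0.436
forearm_r,0.016,0.430
forearm_l,0.016,0.430
hand_r,0.006,0.506
hand_l,0.006,0.506
thigh_r,0.100,0.433
thigh_l,0.100,0.433
shank_r,0.0465,0.433
shank_l,0.0465,0.433
foot_r,0.0145,0.500
foot_l,0.0145,0.500
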