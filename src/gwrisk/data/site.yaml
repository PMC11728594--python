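# Vadose-zone and building parameters for the groundwater-to-air pathways.
# Porosities unitless; lengths in cm; u_air in cm/s; er (air exchange) in 1/s.
theta_a: 0.28
theta_w: 0.15
theta_t: 0.43
l_gw: 300
u_air: 200
delta_air: 200
w: 1000
er: 0.00014
lb: 200
eta: 0.001
l_crack: 15
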