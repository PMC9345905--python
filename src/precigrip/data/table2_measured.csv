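condition,finger,F_i,F_j,F_k,M_k
A_center_fingertip,thumb,0.90,-0.32,-2.62,-0.0001
A_center_fingertip,index,1.05,0.18,2.64,-0.0011
B_far_fingertip,thumb,0.34,-0.26,-8.11,0.0034
B_far_fingertip,index,0.68,-1.30,8.08,-0.0016
C_near_fingertip,thumb,0.16,-0.46,-5.03,-0.0005
C_near_fingertip,index,0.84,-1.09,4.94,-0.0066
D_center_pulp,thumb,0.84,-0.37,-3.70,-0.0033
D_center_pulp,index,1.09,0.32,3.79,-0.0069
E_far_pulp,thumb,0.66,-0.62,-4.06,-0.0063
E_far_pulp,index,1.27,0.63,4.09,0.0029
F_near_pulp,thumb,0.13,-0.66,-3.31,-0.0021
F_near_pulp,index,0.78,-0.92,3.44,-0.0077
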