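condition,finger,F_i,F_j,F_k,M_k
A_center_fingertip,thumb,0.90,-0.63,-3.02,-0.0019
A_center_fingertip,index,1.04,0.54,3.03,-0.0023
B_far_fingertip,thumb,0.55,-0.93,-7.35,-0.0043
B_far_fingertip,index,0.71,-0.55,7.42,-0.0028
C_near_fingertip,thumb,0.34,-0.93,-4.85,-0.0084
C_near_fingertip,index,0.52,-0.81,4.78,-0.0069
D_center_pulp,thumb,1.30,0.32,-3.60,-0.0015
D_center_pulp,index,0.95,-0.19,3.61,-0.0052
E_far_pulp,thumb,1.31,0.36,-3.49,0.0005
E_far_pulp,index,0.64,-0.42,3.51,0.0037
F_near_pulp,thumb,0.98,-0.94,-3.92,0.0007
F_near_pulp,index,-0.19,-0.84,3.90,-0.0110
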