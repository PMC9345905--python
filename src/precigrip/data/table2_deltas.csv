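# Simulated-minus-measured differences as printed in the source comparison table.
# These can differ from recomputed (simulated - measured) by up to 0.01 N / 0.0001 N*m because the
# original differencing was done before rounding the operands.
condition,finger,F_i,F_j,F_k,M_k
A_center_fingertip,thumb,0.00,-0.32,-0.40,-0.0018
A_center_fingertip,index,-0.01,0.35,0.39,-0.0013
B_far_fingertip,thumb,0.21,-0.68,0.77,-0.0078
B_far_fingertip,index,0.03,0.76,-0.66,-0.0012
C_near_fingertip,thumb,0.19,-0.47,0.18,-0.0079
C_near_fingertip,index,-0.32,0.28,-0.17,-0.0003
D_center_pulp,thumb,0.45,0.69,0.10,0.0018
D_center_pulp,index,-0.13,-0.51,-0.18,0.0017
E_far_pulp,thumb,0.65,0.98,0.58,0.0068
E_far_pulp,index,-0.64,-1.05,-0.58,0.0008
F_near_pulp,thumb,0.84,-0.28,-0.61,0.0027
F_near_pulp,index,-0.97,0.09,0.45,-0.0033
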