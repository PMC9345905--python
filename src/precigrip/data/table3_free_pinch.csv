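source,finger,F_i,F_j,F_k,M_k
measured,thumb,0.98,0.52,-3.03,-0.0052
measured,index,0.97,-0.62,3.11,-0.0010
simulated_I,thumb,0.93,0.32,-1.69,0.0000
simulated_I,index,1.01,-0.32,1.69,-0.0002
simulated_II,thumb,0.78,0.02,-1.68,0.0001
simulated_II,index,1.17,-0.02,1.68,-0.0002
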