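name,n,delta_Da,polarity
M-H,1,-1.00782503,-1
2M-H,2,-1.00782503,-1
M-H2O-H,1,-19.01838972,-1
M+Cl,1,34.96885268,-1
M,1,0.00000000,+1
M+H,1,1.00782503,+1
M+Na,1,22.98976928,+1
M+K,1,38.96370668,+1
2M+H,2,1.00782503,+1
2M+Na,2,22.98976928,+1
2M+K,2,38.96370668,+1
M+H-H2O,1,-17.00273965,+1
M+H-2H2O,1,-35.01330434,+1
2M+H-H2O,2,-17.00273965,+1
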