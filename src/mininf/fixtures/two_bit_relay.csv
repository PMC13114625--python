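Z1,Z2,X,Y,p
0,0,0,0,0.25
0,0,0,1,0.0
0,0,1,0,0.0
0,0,1,1,0.0
0,1,0,0,0.0
0,1,0,1,0.25
0,1,1,0,0.0
0,1,1,1,0.0
1,0,0,0,0.0
1,0,0,1,0.0
1,0,1,0,0.25
1,0,1,1,0.0
1,1,0,0,0.0
1,1,0,1,0.0
1,1,1,0,0.0
1,1,1,1,0.25
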