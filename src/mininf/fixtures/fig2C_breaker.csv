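Z,X,Y1,Y2,Y3,W2,W3,p
0,0,0,0,0,0,0,0.125
0,0,0,0,1,0,0,0.0
0,0,0,1,0,0,0,0.125
0,0,0,1,1,0,0,0.0
0,0,1,0,0,0,0,0.0
0,0,1,0,1,0,0,0.0
0,0,1,1,0,0,0,0.0
0,0,1,1,1,0,0,0.0
0,1,0,0,0,0,0,0.0
0,1,0,0,1,0,0,0.0
0,1,0,1,0,0,0,0.0
0,1,0,1,1,0,0,0.0
0,1,1,0,0,0,0,0.0
0,1,1,0,1,0,0,0.0
0,1,1,1,0,0,0,0.0
0,1,1,1,1,0,0,0.0
1,0,0,0,0,0,0,0.0
1,0,0,0,1,0,0,0.125
1,0,0,1,0,0,0,0.0
1,0,0,1,1,0,0,0.125
1,0,1,0,0,0,0,0.0
1,0,1,0,1,0,0,0.0
1,0,1,1,0,0,0,0.0
1,0,1,1,1,0,0,0.0
1,1,0,0,0,0,0,0.0
1,1,0,0,1,0,0,0.0
1,1,0,1,0,0,0,0.0
1,1,0,1,1,0,0,0.0
1,1,1,0,0,0,0,0.0
1,1,1,0,1,0,0,0.0
1,1,1,1,0,0,0,0.0
1,1,1,1,1,0,0,0.0
2,0,0,0,0,0,0,0.0
2,0,0,0,1,0,0,0.0
2,0,0,1,0,0,0,0.0
2,0,0,1,1,0,0,0.0
2,0,1,0,0,0,0,0.0
2,0,1,0,1,0,0,0.0
2,0,1,1,0,0,0,0.0
2,0,1,1,1,0,0,0.0
2,1,0,0,0,0,0,0.0
2,1,0,0,1,0,0,0.0
2,1,0,1,0,0,0,0.0
2,1,0,1,1,0,0,0.0
2,1,1,0,0,0,0,0.125
2,1,1,0,1,0,0,0.0
2,1,1,1,0,0,0,0.125
2,1,1,1,1,0,0,0.0
3,0,0,0,0,0,0,0.0
3,0,0,0,1,0,0,0.0
3,0,0,1,0,0,0,0.0
3,0,0,1,1,0,0,0.0
3,0,1,0,0,0,0,0.0
3,0,1,0,1,0,0,0.0
3,0,1,1,0,0,0,0.0
3,0,1,1,1,0,0,0.0
3,1,0,0,0,0,0,0.0
3,1,0,0,1,0,0,0.0
3,1,0,1,0,0,0,0.0
3,1,0,1,1,0,0,0.0
3,1,1,0,0,0,0,0.0
3,1,1,0,1,0,0,0.125
3,1,1,1,0,0,0,0.0
3,1,1,1,1,0,0,0.125
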