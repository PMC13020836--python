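year,x
1,0.0100
2,0.0090
3,0.0060
4,0.0050
5,0.0040
6,0.0040
7,0.0030
8,0.0030
9,0.0030
10,0.0030
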