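category,0,1-10,11-100,101-400,401-1000,>1000
0,12,7,2,0,0,0
1-10,0,2,13,2,0,0
11-100,0,0,12,18,4,0
101-400,0,0,0,14,49,4
401-1000,0,0,0,0,16,39
>1000,0,0,0,0,0,19
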