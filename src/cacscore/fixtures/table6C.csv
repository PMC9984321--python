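category,0,1-10,11-100,101-400,401-1000,>1000
0,12,5,1,1,0,0
1-10,0,4,4,1,0,0
11-100,0,0,20,8,0,0
101-400,0,0,2,22,16,1
401-1000,0,0,0,2,53,14
>1000,0,0,0,0,0,47
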