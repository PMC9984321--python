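category,count
0,12
1-10,9
11-100,27
101-400,34
401-1000,69
>1000,62
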