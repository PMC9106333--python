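# Raw cytoarchitectonic area -> analysis group (frontal + insular cortex, 27 -> 19)
name,group
10,10
10d,10
25,25
14o,14
14m,14
11,11
13,13
13a,13
24a,24
24b,24
32,32
46v,46
46d,46
9l,9
9/46v,9
9/46d,9
8a,8
8b,8
6m,6m
6d,6d
6v,6v
OPAl,OPAl
OPro,OPro
AI,AI
DI,DI
GI,GI
IPro,IPro
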