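# Synthetic demonstration volume table (mm^3). Area volumes are input data for the
# volume-weighted chance null; these values are plausible for macaque frontal and
# insular cytoarchitectonic areas but are NOT measured atlas volumes.
name,group,volume_mm3
10,10,95
10d,10,60
25,25,40
14o,14,45
14m,14,50
11,11,180
13,13,150
13a,13,35
24a,24,80
24b,24,90
32,32,55
46v,46,140
46d,46,150
9l,9,110
9/46v,9,95
9/46d,9,100
8a,8,160
8b,8,120
6m,6m,130
6d,6d,170
6v,6v,150
OPAl,OPAl,45
OPro,OPro,60
AI,AI,85
DI,DI,40
GI,GI,35
IPro,IPro,30
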