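subject,retic_volume_fl,total_volume_fl,retic_hb_pg,total_hb_pg,retic_conc_gdl,total_conc_gdl
1,103.6,86.3,34.2,30.3,33.5,35.2
2,109.8,88.6,33.3,30.2,30.6,34.2
3,104.7,91.2,33.8,31.7,32.7,34.9
4,103.6,85.5,34.2,30.4,33.2,35.8
5,111.1,95.0,36.8,32.2,33.4,34.1
6,107.8,91.6,33.2,30.7,30.9,33.6
7,114.8,96.8,35.1,33.0,30.7,34.3
8,105.3,89.2,33.3,31.0,31.8,35.0
9,97.3,84.4,29.3,26.8,30.3,31.9
10,101.7,86.6,33.6,30.9,33.2,35.9
11,100.5,82.8,32.3,28.5,32.7,34.6
12,107.6,93.1,34.9,32.6,32.7,35.2
13,102.5,84.4,33.1,29.3,32.5,34.9
14,105.2,88.1,32.2,29.8,30.8,33.9
15,104.1,90.2,32.0,29.7,31.1,33.0
16,108.1,91.0,33.4,29.7,31.0,32.8
17,107.0,90.3,33.4,30.8,31.3,34.3
18,111.2,95.0,34.0,31.0,30.8,32.7
19,103.3,83.8,34.0,30.2,33.3,36.2
20,103.6,90.9,32.4,30.7,31.5,33.8
21,103.0,86.1,32.8,30.2,32.0,35.2
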