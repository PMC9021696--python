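subject,HbO,CSP,R-CSP-E,R-CSP-CV
1,45.0,51.7,58.3,50.0
2,71.7,63.3,66.7,65.0
3,63.3,55.0,61.7,53.3
4,60.0,61.7,68.3,63.3
5,61.7,65.0,71.7,58.3
6,48.3,50.0,58.3,51.7
7,61.7,63.3,68.3,65.0
8,66.7,68.3,71.7,63.3
9,55.0,61.3,66.7,58.3
10,60.0,55.0,63.3,56.7
11,55.0,61.3,68.3,63.3
12,58.3,63.3,65.0,55.0
13,61.7,60.0,68.3,58.3
14,55.0,68.3,71.7,65.0
15,61.7,63.3,70.0,65.0
16,60.0,66.7,68.3,61.7
17,48.3,50.0,58.3,53.3
18,53.3,63.3,73.3,60.0
19,55.0,58.3,61.7,55.0
20,61.7,65.0,68.3,58.3
21,63.3,70.0,65.0,61.7
22,51.7,55.0,58.3,51.3
23,68.3,65.0,71.7,65.0
24,51.7,53.3,63.3,55.0
25,60.0,51.7,65.0,48.3
26,61.7,65.0,73.3,65.0
27,58.3,63.3,68.3,61.7
28,68.3,66.7,71.7,65.0
29,66.7,63.3,73.3,58.3
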