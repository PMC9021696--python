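subject,CSP,R-CSP-CV,R-CSP-E
1,83.3,78.3,85.0
2,65.0,71.7,78.3
3,75.0,73.3,83.3
4,71.7,75.0,76.7
5,66.7,65.0,75.0
6,63.3,66.7,70.0
7,71.7,75.0,81.7
8,68.3,68.3,75.0
9,75.0,71.7,78.3
10,80.0,78.3,83.3
11,71.3,75.0,78.3
12,76.7,78.3,83.3
13,63.3,65.0,70.0
14,71.7,76.7,81.7
15,68.3,73.3,75.0
16,71.7,78.3,85.0
17,55.0,61.3,73.3
18,81.3,78.3,86.7
19,68.3,70.0,78.3
20,66.7,71.7,68.3
21,71.7,78.3,83.3
22,58.3,61.3,65.0
23,73.3,65.0,75.0
24,65.0,76.7,81.7
25,75.0,71.7,80.0
26,81.3,85.0,91.7
27,71.7,73.3,80.0
28,56.7,55.0,63.3
29,68.3,75.0,81.7
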