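item,subscale
1,stress
2,anxiety
3,depression
4,anxiety
5,depression
6,stress
7,anxiety
8,stress
9,anxiety
10,depression
11,stress
12,stress
13,depression
14,stress
15,anxiety
16,depression
17,depression
18,stress
19,anxiety
20,anxiety
21,depression
22,stress
23,anxiety
24,depression
25,anxiety
26,depression
27,stress
28,anxiety
29,stress
30,anxiety
31,depression
32,stress
33,stress
34,depression
35,stress
36,anxiety
37,depression
38,depression
39,stress
40,anxiety
41,anxiety
42,depression
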