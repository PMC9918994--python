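participant,final_score
1,0.80400957
2,0.76927435
3,0.62282284
4,0.74328593
5,0.74373664
6,0.70207034
7,0.64074447
8,0.73227387
9,0.70003183
10,0.72986779
11,0.70734059
12,0.69860786
13,0.65737016
14,0.66614456
15,0.69351383
16,0.67523309
17,0.68521024
18,0.66333946
19,0.71704625
20,0.67574448
21,0.70851757
22,0.74564416
23,0.68427606
24,0.64150353
25,0.71149862
26,0.6788365
27,0.68999421
28,0.72515522
29,0.61814783
30,0.7283098
31,0.70268278
32,0.60633094
33,0.61681826
34,0.64672526
35,0.67162273
36,0.73704441
37,0.69031519
38,0.6860709
39,0.77480748
40,0.73948592
41,0.82803729
42,0.75687176
43,0.65334806
44,0.65969457
45,0.69795882
46,0.77084335
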