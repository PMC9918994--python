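participant,final_score
1,0.76734109
2,0.65589328
3,0.64234552
4,0.69709596
5,0.73758406
6,0.68142442
7,0.60856813
8,0.60663099
9,0.53337415
10,0.65551133
11,0.60379564
12,0.67940767
13,0.6983585
14,0.75756501
15,0.74477273
16,0.74373664
17,0.69312008
18,0.64302757
19,0.64844364
20,0.71791784
21,0.6558216
22,0.62666147
23,0.6727858
24,0.70166569
25,0.73768627
26,0.65344389
27,0.61765752
28,0.74812219
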