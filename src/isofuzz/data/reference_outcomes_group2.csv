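participant,final_score
1,0.56585384
2,0.64469192
3,0.54099616
4,0.61011369
5,0.56910691
6,0.58987825
7,0.56994588
8,0.5731141
9,0.56502047
10,0.61102068
11,0.54596697
12,0.61948461
13,0.62375196
14,0.66939015
15,0.575458
16,0.58376321
17,0.59714431
18,0.59057348
19,0.58581099
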