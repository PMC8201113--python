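attr_id,n_A,n_Q,n_I,n_R,n_M,n_O
1,24,0,21,0,85,120
2,12,0,4,0,74,160
3,2,0,8,0,99,141
4,10,1,9,0,98,132
5,7,0,3,0,78,162
6,4,0,2,0,70,174
7,4,1,2,0,91,152
8,8,0,4,1,89,148
9,17,0,10,2,94,127
10,5,0,3,2,72,168
11,1,0,6,1,98,144
12,5,0,2,1,75,167
13,3,0,5,2,88,152
14,8,0,0,1,86,155
15,6,0,4,0,56,184
16,8,0,1,0,81,160
17,7,0,4,0,72,167
18,10,0,5,0,62,173
19,11,0,9,0,58,172
20,9,0,3,0,63,175
21,2,0,3,0,127,118
22,3,0,11,0,122,114
23,2,0,14,0,98,136
24,8,0,2,1,52,187
25,5,1,10,2,101,131
26,3,0,9,2,131,105
27,4,1,7,3,90,145
28,5,0,5,5,53,182
29,2,0,35,3,104,106
30,14,1,23,2,88,122
31,0,1,28,220,1,0
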