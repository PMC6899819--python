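study,treatment,events,size
1,7,27,84
1,1,1,38
2,7,34,88
2,1,0,43
3,3,62,88
3,1,4,51
4,3,12,65
4,1,1,30
5,2,48,61
5,1,21,54
6,2,10,17
6,1,2,16
7,2,13,15
7,1,1,12
8,2,18,68
8,1,1,33
9,2,10,11
9,1,0,11
10,2,11,13
10,1,0,12
11,2,2,10
11,1,0,10
12,6,62,173
12,1,16,78
13,6,62,76
13,1,3,33
14,6,50,62
14,1,1,30
15,8,13,16
15,1,3,17
16,4,29,92
16,1,5,44
17,5,11,40
17,1,4,33
18,5,2,17
18,1,1,15
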