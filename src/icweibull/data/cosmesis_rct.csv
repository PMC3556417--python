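left,right
8,12
0,22
24,31
17,27
17,23
24,30
16,24
13,Inf
11,13
16,20
18,25
17,26
32,Inf
23,Inf
44,48
14,17
0,5
5,8
12,20
11,Inf
33,40
31,Inf
13,39
19,32
34,Inf
13,Inf
16,24
35,Inf
15,22
11,17
22,32
10,35
30,34
13,Inf
10,17
8,21
4,9
11,Inf
14,19
4,8
34,Inf
30,36
18,24
16,60
35,39
21,Inf
11,20
48,Inf
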