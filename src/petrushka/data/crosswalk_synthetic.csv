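phq9,hdrs
0,0
1,1
2,3
3,4
4,6
5,8
6,9
7,11
8,13
9,14
10,16
11,18
12,19
13,21
14,23
15,25
16,27
17,29
18,31
19,33
20,35
21,37
22,39
23,41
24,43
25,45
26,48
27,50
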