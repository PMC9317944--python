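col68,colP
17,0
18,1
19,2
20,3
21,4
22,5
23,6
24,7
25,8
26,9
36,10
37,11
38,12
39,13
40,14
41,15
42,16
43,17
44,18
45,19
46,20
47,21
27,22
31,23
32,24
33,25
34,26
35,27
48,28
49,29
50,30
51,31
52,32
53,33
54,34
55,35
56,36
57,37
58,38
59,39
60,40
61,41
62,42
63,43
64,44
65,45
66,46
67,47
28,48
29,49
30,50
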