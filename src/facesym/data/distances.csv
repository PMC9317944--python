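name,kind,points
A,pair,10 19
Bl,pair,10 13
Br,pair,16 19
C,pair,13 16
D,pair,11 15
E,pair,18 20
F,pair,23 28
G,pair,27 34
H,pair,0 4
I,pair,5 9
J,pair,2 28
K,pair,7 34
Nl,pair,0 10
Nr,pair,4 13
Ol,pair,5 16
Or,pair,9 19
Pl,pair,28 37
Pu,pair,28 31
Ql,pair,34 37
Qu,pair,31 34
R,pair,10 22
S,pair,19 22
T,pair,10 25
U,pair,19 25
Vl,pair,10 28
Vr,pair,19 34
W,pair,28 34
X,pair,22 25
L,brow_height,0 1 2 3 4
M,brow_height,5 6 7 8 9
Wl,perimeter,28 29 30 31 37 38 39
Wr,perimeter,31 32 33 34 35 36 37
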