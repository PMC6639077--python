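residue	probability
A	0.0548
R	0.0445
N	0.0615
D	0.0580
C	0.0132
Q	0.0394
E	0.0649
G	0.0498
H	0.0217
I	0.0655
L	0.0958
K	0.0730
M	0.0207
F	0.0449
P	0.0438
S	0.0898
T	0.0591
W	0.0104
Y	0.0338
V	0.0564
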