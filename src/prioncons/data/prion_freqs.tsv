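residue	probability
A	0.050
R	0.020
N	0.200
D	0.030
C	0.003
Q	0.180
E	0.030
G	0.080
H	0.015
I	0.020
L	0.035
K	0.030
M	0.020
F	0.030
P	0.050
S	0.090
T	0.040
W	0.005
Y	0.050
V	0.025
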