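residue	propensity
A	1.00
R	0.95
L	0.90
M	0.88
K	0.86
Q	0.80
E	0.78
I	0.75
W	0.70
S	0.65
Y	0.62
F	0.60
H	0.55
V	0.50
C	0.45
N	0.42
T	0.40
D	0.35
G	0.10
P	0.00
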