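# SYNTHETIC bilayer-context hydrophobicity scale (kcal/mol): a linear
# transform of the octanol scale (slope 1.8, intercept -0.6) with small
# residue offsets, standing in for experimentally measured values.
residue	dG_wl
A	0.20
R	2.86
N	1.08
C	-0.69
Q	0.84
G	1.57
H	3.44
I	-2.67
L	-2.80
K	4.74
M	-1.71
F	-3.78
P	-0.10
S	0.18
T	-0.10
W	-4.21
Y	-2.08
V	-1.33
D	1.00
E	0.60
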