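# Wimley-White water-to-octanol side-chain transfer scale (kcal/mol).
residue	dG_wl
A	0.50
R	1.81
N	0.85
D	3.64
C	-0.02
Q	0.77
E	3.63
G	1.15
H	2.33
I	-1.12
L	-1.25
K	2.80
M	-0.67
F	-1.71
P	0.14
S	0.46
T	0.25
W	-2.09
Y	-0.71
V	-0.46
D-1	3.64
E-1	3.63
D0	0.43
E0	0.11
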