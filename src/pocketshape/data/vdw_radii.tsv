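# van der Waals radii by element symbol (Angstrom), Bondi-style set
# element	radius
H	1.20
C	1.70
N	1.55
O	1.52
F	1.47
P	1.80
S	1.80
CL	1.75
BR	1.85
I	1.98
SE	1.90
B	1.92
SI	2.10
ZN	1.39
CA	2.31
MG	1.73
MN	2.05
FE	2.05
NA	2.27
K	2.75
CU	1.40
NI	1.63
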