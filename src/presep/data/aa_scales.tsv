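aa	hydrophobicity	hydrophilicity	side_chain_mass	pK_alpha_COOH	pK_alpha_NH3	pI_25C
A	0.62	-0.5	15.0	2.35	9.87	6.11
C	0.29	-1.0	47.0	1.71	10.78	5.02
D	-0.90	3.0	59.0	1.88	9.60	2.98
E	-0.74	3.0	73.0	2.19	9.67	3.08
F	1.19	-2.5	91.0	2.58	9.24	5.91
G	0.48	0.0	1.0	2.34	9.60	6.06
H	-0.40	-0.5	82.0	1.78	8.97	7.64
I	1.38	-1.8	57.0	2.32	9.76	6.04
K	-1.50	3.0	73.0	2.20	8.90	9.47
L	1.06	-1.8	57.0	2.36	9.60	6.04
M	0.64	-1.3	75.0	2.28	9.21	5.74
N	-0.78	0.2	58.0	2.18	9.09	5.41
P	0.12	0.0	42.0	1.99	10.60	6.30
Q	-0.85	0.2	72.0	2.17	9.13	5.65
R	-2.53	3.0	101.0	2.18	9.09	10.76
S	-0.18	0.3	31.0	2.21	9.15	5.68
T	-0.05	-0.4	45.0	2.15	9.12	5.60
V	1.08	-1.5	43.0	2.29	9.74	6.02
W	0.81	-3.4	130.0	2.38	9.39	5.88
Y	0.26	-2.3	107.0	2.20	9.11	5.63
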