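# Six beta-galactosidases expressed in P. pastoris GS115: predicted secretion
# propensity (Type I PseAAC, w=0.05, lambda=19) and measured extracellular
# activity as a percentage of total beta-galactosidase activity.
protein	propensity	extracellular_pct
LacB	0.90	92.3
CelB	0.35	7.0
BglKL	0.50	30.2
BglZQ	0.18	0.4
GalC168	0.23	5.8
BG42-106	0.23	0.2
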