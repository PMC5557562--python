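# Per-residue intrinsic-disorder propensity used by the built-in synthetic
# disorder provider (a deterministic stand-in, NOT a trained disorder
# predictor). Values are the TOP-IDP scale (Campen et al. 2008); higher =
# more disorder promoting.
residue	value
A	0.060
C	0.020
D	0.192
E	0.736
F	-0.697
G	0.166
H	0.303
I	-0.486
K	0.586
L	-0.326
M	-0.397
N	0.007
P	0.987
Q	0.318
R	0.180
S	0.341
T	0.059
V	-0.121
W	-0.884
Y	-0.510
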