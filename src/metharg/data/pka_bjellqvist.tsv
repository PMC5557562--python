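# Bjellqvist-style pKa set for peptide net-charge and pI calculation
# (Bjellqvist et al. 1993, as adopted by common charge/pI implementations).
# sign: +1 for groups positive when protonated (bases), -1 for groups
# negative when deprotonated (acids).
group	pka	sign
nterm	7.50	1
cterm	3.55	-1
C	9.00	-1
D	4.05	-1
E	4.45	-1
H	5.98	1
K	10.00	1
R	12.00	1
Y	10.00	-1
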