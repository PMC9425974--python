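# Robinson & Robinson amino-acid background frequencies (relative, per 1000
# residues in the original tabulation; normalized to sum 1 on load).
A	78.05
R	51.29
N	44.87
D	53.64
C	19.25
Q	42.64
E	62.95
G	73.77
H	21.99
I	51.42
L	90.51
K	57.44
M	22.43
F	38.56
P	52.03
S	71.20
T	58.41
W	13.30
Y	32.16
V	64.41
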