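# Per-residue biophysical descriptors used to numericise an alignment.
# r_group_mass: average side-chain mass in Daltons (free amino acid minus
#   the glycine backbone, i.e. glycine's side chain is a single H).
# net_charge: formal side-chain charge at pH 7 (D/E -1, K/R +1, H +0.1
#   for partial imidazole protonation; override via PropertyTable).
# hydropathy: Kyte-Doolittle hydropathy index.
# top_idp: TOP-IDP intrinsic disorder propensity scale.
aa	r_group_mass	net_charge	hydropathy	top_idp
A	15.035	0	1.8	0.060
R	100.145	1	-4.5	0.180
N	58.060	0	-3.5	0.007
D	59.044	-1	-3.5	0.192
C	47.095	0	2.5	0.020
Q	72.087	0	-3.5	0.318
E	73.071	-1	-3.5	0.736
G	1.008	0	-0.4	0.166
H	81.098	0.1	-3.2	0.303
I	57.116	0	4.5	-0.486
L	57.116	0	3.8	-0.326
K	72.131	1	-3.9	0.586
M	75.149	0	1.9	-0.397
F	91.133	0	2.8	-0.697
P	42.081	0	-1.6	0.987
S	31.034	0	-0.8	0.341
T	45.061	0	-0.7	0.059
W	130.170	0	-0.9	-0.884
Y	107.132	0	-1.3	-0.510
V	43.089	0	4.2	-0.121
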