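# Amino-acid background frequencies of Dayhoff, Schwartz & Orcutt (1978),
# the equilibrium composition of the PAM evolutionary model.
A	0.08713
R	0.04090
N	0.04043
D	0.04687
C	0.03347
Q	0.03826
E	0.04953
G	0.08861
H	0.03362
I	0.03689
L	0.08536
K	0.08048
M	0.01475
F	0.03977
P	0.05068
S	0.06958
T	0.05854
W	0.01049
Y	0.02992
V	0.06472
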