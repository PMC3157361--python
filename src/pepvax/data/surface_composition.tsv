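# amino-acid frequencies on general protein surfaces (bundled default)
aa	freq
A	0.084
C	0.010
D	0.069
E	0.082
F	0.030
G	0.069
H	0.022
I	0.038
K	0.082
L	0.076
M	0.017
N	0.045
P	0.052
Q	0.041
R	0.052
S	0.076
T	0.066
V	0.046
W	0.013
Y	0.030
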