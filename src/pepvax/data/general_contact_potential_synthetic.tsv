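# synthetic general-purpose residue contact score table
# (Kyte-Doolittle hydrophobicity products, scaled to [-1, 1];
#  an immune-nonspecific stand-in used only for comparison runs)
# rows = receptor amino acid, columns = ligand amino acid
	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0.1600	0.2222	-0.3111	-0.3111	0.2489	-0.0356	-0.2844	0.4000	-0.3467	0.3378	0.1689	-0.3111	-0.1422	-0.3111	-0.4000	-0.0711	-0.0622	0.3733	-0.0800	-0.1156
C	0.2222	0.3086	-0.4321	-0.4321	0.3457	-0.0494	-0.3951	0.5556	-0.4815	0.4691	0.2346	-0.4321	-0.1975	-0.4321	-0.5556	-0.0988	-0.0864	0.5185	-0.1111	-0.1605
D	-0.3111	-0.4321	0.6049	0.6049	-0.4840	0.0691	0.5531	-0.7778	0.6741	-0.6568	-0.3284	0.6049	0.2765	0.6049	0.7778	0.1383	0.1210	-0.7259	0.1556	0.2247
E	-0.3111	-0.4321	0.6049	0.6049	-0.4840	0.0691	0.5531	-0.7778	0.6741	-0.6568	-0.3284	0.6049	0.2765	0.6049	0.7778	0.1383	0.1210	-0.7259	0.1556	0.2247
F	0.2489	0.3457	-0.4840	-0.4840	0.3872	-0.0553	-0.4425	0.6222	-0.5393	0.5254	0.2627	-0.4840	-0.2212	-0.4840	-0.6222	-0.1106	-0.0968	0.5807	-0.1244	-0.1798
G	-0.0356	-0.0494	0.0691	0.0691	-0.0553	0.0079	0.0632	-0.0889	0.0770	-0.0751	-0.0375	0.0691	0.0316	0.0691	0.0889	0.0158	0.0138	-0.0830	0.0178	0.0257
H	-0.2844	-0.3951	0.5531	0.5531	-0.4425	0.0632	0.5057	-0.7111	0.6163	-0.6005	-0.3002	0.5531	0.2528	0.5531	0.7111	0.1264	0.1106	-0.6637	0.1422	0.2054
I	0.4000	0.5556	-0.7778	-0.7778	0.6222	-0.0889	-0.7111	1.0000	-0.8667	0.8444	0.4222	-0.7778	-0.3556	-0.7778	-1.0000	-0.1778	-0.1556	0.9333	-0.2000	-0.2889
K	-0.3467	-0.4815	0.6741	0.6741	-0.5393	0.0770	0.6163	-0.8667	0.7511	-0.7319	-0.3659	0.6741	0.3081	0.6741	0.8667	0.1541	0.1348	-0.8089	0.1733	0.2504
L	0.3378	0.4691	-0.6568	-0.6568	0.5254	-0.0751	-0.6005	0.8444	-0.7319	0.7131	0.3565	-0.6568	-0.3002	-0.6568	-0.8444	-0.1501	-0.1314	0.7881	-0.1689	-0.2440
M	0.1689	0.2346	-0.3284	-0.3284	0.2627	-0.0375	-0.3002	0.4222	-0.3659	0.3565	0.1783	-0.3284	-0.1501	-0.3284	-0.4222	-0.0751	-0.0657	0.3941	-0.0844	-0.1220
N	-0.3111	-0.4321	0.6049	0.6049	-0.4840	0.0691	0.5531	-0.7778	0.6741	-0.6568	-0.3284	0.6049	0.2765	0.6049	0.7778	0.1383	0.1210	-0.7259	0.1556	0.2247
P	-0.1422	-0.1975	0.2765	0.2765	-0.2212	0.0316	0.2528	-0.3556	0.3081	-0.3002	-0.1501	0.2765	0.1264	0.2765	0.3556	0.0632	0.0553	-0.3319	0.0711	0.1027
Q	-0.3111	-0.4321	0.6049	0.6049	-0.4840	0.0691	0.5531	-0.7778	0.6741	-0.6568	-0.3284	0.6049	0.2765	0.6049	0.7778	0.1383	0.1210	-0.7259	0.1556	0.2247
R	-0.4000	-0.5556	0.7778	0.7778	-0.6222	0.0889	0.7111	-1.0000	0.8667	-0.8444	-0.4222	0.7778	0.3556	0.7778	1.0000	0.1778	0.1556	-0.9333	0.2000	0.2889
S	-0.0711	-0.0988	0.1383	0.1383	-0.1106	0.0158	0.1264	-0.1778	0.1541	-0.1501	-0.0751	0.1383	0.0632	0.1383	0.1778	0.0316	0.0277	-0.1659	0.0356	0.0514
T	-0.0622	-0.0864	0.1210	0.1210	-0.0968	0.0138	0.1106	-0.1556	0.1348	-0.1314	-0.0657	0.1210	0.0553	0.1210	0.1556	0.0277	0.0242	-0.1452	0.0311	0.0449
V	0.3733	0.5185	-0.7259	-0.7259	0.5807	-0.0830	-0.6637	0.9333	-0.8089	0.7881	0.3941	-0.7259	-0.3319	-0.7259	-0.9333	-0.1659	-0.1452	0.8711	-0.1867	-0.2696
W	-0.0800	-0.1111	0.1556	0.1556	-0.1244	0.0178	0.1422	-0.2000	0.1733	-0.1689	-0.0844	0.1556	0.0711	0.1556	0.2000	0.0356	0.0311	-0.1867	0.0400	0.0578
Y	-0.1156	-0.1605	0.2247	0.2247	-0.1798	0.0257	0.2054	-0.2889	0.2504	-0.2440	-0.1220	0.2247	0.1027	0.2247	0.2889	0.0514	0.0449	-0.2696	0.0578	0.0835
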