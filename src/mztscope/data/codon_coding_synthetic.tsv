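triplet	frequency
AAA	3.000000
AAC	38.000000
AAG	57.000000
AAT	2.000000
ACA	2.200000
ACC	48.400000
ACG	2.200000
ACT	2.200000
AGA	1.650000
AGC	63.750000
AGG	1.650000
AGT	2.250000
ATA	2.000000
ATC	46.000000
ATG	23.000000
ATT	2.000000
CAA	2.250000
CAC	23.750000
CAG	42.750000
CAT	1.250000
CCA	2.200000
CCC	48.400000
CCG	2.200000
CCT	2.200000
CGA	1.650000
CGC	46.750000
CGG	1.650000
CGT	1.650000
CTA	2.850000
CTC	80.750000
CTG	2.850000
CTT	2.850000
GAA	3.250000
GAC	47.500000
GAG	61.750000
GAT	2.500000
GCA	2.800000
GCC	61.600000
GCG	2.800000
GCT	2.800000
GGA	2.600000
GGC	57.200000
GGG	2.600000
GGT	2.600000
GTA	2.600000
GTC	57.200000
GTG	2.600000
GTT	2.600000
TAA	0.200000
TAC	28.500000
TAG	4.600000
TAT	1.500000
TCA	2.250000
TCC	2.250000
TCG	2.250000
TCT	2.250000
TGA	0.200000
TGC	19.000000
TGG	12.000000
TGT	1.000000
TTA	2.850000
TTC	38.000000
TTG	2.850000
TTT	2.000000
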