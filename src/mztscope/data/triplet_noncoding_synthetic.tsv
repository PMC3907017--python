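triplet	frequency
AAA	27.000000
AAC	18.000000
AAG	18.000000
AAT	27.000000
ACA	18.000000
ACC	12.000000
ACG	12.000000
ACT	18.000000
AGA	18.000000
AGC	12.000000
AGG	12.000000
AGT	18.000000
ATA	27.000000
ATC	18.000000
ATG	18.000000
ATT	27.000000
CAA	18.000000
CAC	12.000000
CAG	12.000000
CAT	18.000000
CCA	12.000000
CCC	8.000000
CCG	8.000000
CCT	12.000000
CGA	12.000000
CGC	8.000000
CGG	8.000000
CGT	12.000000
CTA	18.000000
CTC	12.000000
CTG	12.000000
CTT	18.000000
GAA	18.000000
GAC	12.000000
GAG	12.000000
GAT	18.000000
GCA	12.000000
GCC	8.000000
GCG	8.000000
GCT	12.000000
GGA	12.000000
GGC	8.000000
GGG	8.000000
GGT	12.000000
GTA	18.000000
GTC	12.000000
GTG	12.000000
GTT	18.000000
TAA	27.000000
TAC	18.000000
TAG	18.000000
TAT	27.000000
TCA	18.000000
TCC	12.000000
TCG	12.000000
TCT	18.000000
TGA	18.000000
TGC	12.000000
TGG	12.000000
TGT	18.000000
TTA	27.000000
TTC	18.000000
TTG	18.000000
TTT	27.000000
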