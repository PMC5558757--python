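kmer	value
AAA	-0.274
AAC	-0.2395
AAG	-0.1775
AAT	-0.277
ACA	-0.095
ACC	-0.1185
ACG	-0.119
ACT	-0.143
AGA	-0.059
AGC	-0.0025
AGG	-0.0565
AGT	-0.143
ATA	-0.049
ATC	-0.1585
ATG	-0.1325
ATT	-0.277
CAA	-0.1295
CAC	-0.095
CAG	-0.033
CAT	-0.1325
CCA	-0.0085
CCC	-0.032
CCG	-0.0325
CCT	-0.0565
CGA	-0.035
CGC	0.0215
CGG	-0.0325
CGT	-0.119
CTA	0.0505
CTC	-0.059
CTG	-0.033
CTT	-0.1775
GAA	-0.1555
GAC	-0.121
GAG	-0.059
GAT	-0.1585
GCA	0.0455
GCC	0.022
GCG	0.0215
GCT	-0.0025
GGA	-0.0345
GGC	0.022
GGG	-0.032
GGT	-0.1185
GTA	-0.0115
GTC	-0.121
GTG	-0.095
GTT	-0.2395
TAA	-0.046
TAC	-0.0115
TAG	0.0505
TAT	-0.049
TCA	-0.011
TCC	-0.0345
TCG	-0.035
TCT	-0.059
TGA	-0.011
TGC	0.0455
TGG	-0.0085
TGT	-0.095
TTA	-0.046
TTC	-0.1555
TTG	-0.1295
TTT	-0.274
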