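kmer	value
AAA	-0.18
AAC	-0.12
AAG	-0.06
AAT	-0.24
ACA	0.0
ACC	0.035
ACG	0.095
ACT	0.0
AGA	0.07
AGC	0.175
AGG	0.095
AGT	0.0
ATA	-0.33
ATC	-0.11
ATG	-0.12
ATT	-0.24
CAA	-0.06
CAC	0.0
CAG	0.06
CAT	-0.12
CCA	0.095
CCC	0.13
CCG	0.19
CCT	0.095
CGA	0.165
CGC	0.27
CGG	0.19
CGT	0.095
CTA	-0.15
CTC	0.07
CTG	0.06
CTT	-0.06
GAA	-0.05
GAC	0.01
GAG	0.07
GAT	-0.11
GCA	0.175
GCC	0.21
GCG	0.27
GCT	0.175
GGA	0.105
GGC	0.21
GGG	0.13
GGT	0.035
GTA	-0.21
GTC	0.01
GTG	0.0
GTT	-0.12
TAA	-0.27
TAC	-0.21
TAG	-0.15
TAT	-0.33
TCA	0.07
TCC	0.105
TCG	0.165
TCT	0.07
TGA	0.07
TGC	0.175
TGG	0.095
TGT	0.0
TTA	-0.27
TTC	-0.05
TTG	-0.06
TTT	-0.18
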