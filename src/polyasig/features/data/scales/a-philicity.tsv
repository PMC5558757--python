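kmer	value
AA	0.29
AC	0.95
AG	0.66
AT	0.11
CA	0.8
CC	1.44
CG	1.86
CT	0.66
GA	1.04
GC	2.42
GG	1.44
GT	0.95
TA	0.03
TC	1.04
TG	0.8
TT	0.29
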