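kmer	value
AA	1.18
AC	1.06
AG	1.06
AT	1.12
CA	1.06
CC	0.99
CG	1.02
CT	1.06
GA	1.08
GC	0.98
GG	0.99
GT	1.06
TA	1.07
TC	1.08
TG	1.06
TT	1.18
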