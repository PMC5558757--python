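kmer	value
AA	1.04
AC	1.1
AG	1.09
AT	1.02
CA	1.16
CC	1.27
CG	1.25
CT	1.09
GA	1.12
GC	1.17
GG	1.27
GT	1.1
TA	1.05
TC	1.12
TG	1.16
TT	1.04
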