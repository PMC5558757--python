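kmer	value
AA	35.62
AC	34.4
AG	27.7
AT	31.5
CA	34.5
CC	33.67
CG	29.8
CT	27.7
GA	36.9
GC	40.0
GG	33.67
GT	34.4
TA	36.0
TC	36.9
TG	34.5
TT	35.62
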