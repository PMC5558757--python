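kmer	value
AA	66.51
AC	108.8
AG	85.12
AT	72.29
CA	64.92
CC	99.31
CG	80.8
CT	85.12
GA	80.38
GC	135.83
GG	99.31
GT	108.8
TA	50.11
TC	80.38
TG	64.92
TT	66.51
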