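kmer	value
AA	54.5
AC	97.73
AG	58.42
AT	57.02
CA	54.71
CC	85.97
CG	72.55
CT	58.42
GA	86.44
GC	136.12
GG	85.97
GT	97.73
TA	36.73
TC	86.44
TG	54.71
TT	54.5
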