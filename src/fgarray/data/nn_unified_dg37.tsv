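# Unified oligonucleotide nearest-neighbor free energies, dG37 in kcal/mol
# (SantaLucia 1998 unified parameter set). Stacks are 5'->3' dinucleotides
# on the top strand of a perfectly matched duplex. init/A etc. are duplex
# initiation terms per terminal base pair.
stack	dg
AA	-1.00
AT	-0.88
AC	-1.44
AG	-1.28
TA	-0.58
TT	-1.00
TC	-1.30
TG	-1.45
CA	-1.45
CT	-1.28
CC	-1.84
CG	-2.17
GA	-1.30
GT	-1.44
GC	-2.24
GG	-1.84
init/A	1.03
init/T	1.03
init/C	0.98
init/G	0.98
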