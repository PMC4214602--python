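# Nearest-neighbor dG37 parameters for RNA/DNA hybrid duplexes (kcal/mol)
# Sugimoto et al. (1995) Biochemistry 34:11211.
# Step keyed 5'->3' on the RNA strand (rXY paired to its DNA complement).
AA	-1.0
AC	-2.1
AG	-1.8
AU	-0.9
CA	-0.9
CC	-2.1
CG	-1.7
CU	-0.9
GA	-1.3
GC	-2.7
GG	-2.9
GU	-1.1
UA	-0.6
UC	-1.5
UG	-1.6
UU	-0.2
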