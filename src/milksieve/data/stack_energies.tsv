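# Nearest-neighbor stack free energies, kcal/mol at 37 C.
# Columns: pair1 pair2 energy.  A pair "XY" means X on the 5'->3' strand
# paired with Y; the stack (pair1, pair2) reads 5'-X1 X2-3' over 3'-Y1 Y2-5'.
# DNA letters encode RNA pairs (U -> T): GT/TG are the G.U wobble images.
# The table lists one spelling per physical stack; helix-reversal symmetry
# (pair1,pair2) == (reverse(pair2), reverse(pair1)) fills in the rest.
AT	AT	-0.93
AT	TA	-1.10
TA	AT	-1.33
CG	TA	-2.08
CG	AT	-2.11
GC	TA	-2.24
GC	AT	-2.35
CG	GC	-2.36
GC	GC	-3.26
GC	CG	-3.42
AT	GT	-0.55
AT	TG	-1.36
CG	GT	-1.41
CG	TG	-2.11
GC	GT	-1.53
GC	TG	-2.51
TA	GT	-1.27
TA	TG	-1.00
GT	GT	0.47
GT	TG	0.30
TG	GT	-0.57
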