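# Minimal ideal-geometry subset for the 20 standard amino acids
# (Engh-Huber-style backbone + CB values; side chains beyond CB are not
# restrained here and are skipped in bond/angle RMS).
# kind	resname	atoms	value
bond	*	N-CA	1.458
bond	*	CA-C	1.525
bond	*	C-O	1.231
bond	*	CA-CB	1.530
angle	*	N-CA-C	111.2
angle	*	CA-C-O	120.8
angle	*	N-CA-CB	110.4
link_bond	*	C-N	1.329
link_angle	*	CA-C-N	116.2
link_angle	*	C-N-CA	121.7
vdw	H	1.20
vdw	C	1.70
vdw	N	1.55
vdw	O	1.52
vdw	S	1.80
vdw	SE	1.90
vdw	P	1.80
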