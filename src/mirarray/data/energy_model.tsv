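# RNA/RNA nearest-neighbor duplex parameters, kcal/mol at 37 C.
# Stack keys are written top/bottom with BOTH strands 5'->3', so key XY/WZ
# stacks the pairs X:Z and Y:W. Watson-Crick/Watson-Crick doublets carry the
# standard Turner/Xia free energies; doublets involving G:U wobbles use a
# compact class-based approximation (wobble+CG -1.40, wobble+AU -0.80,
# wobble+wobble +0.50). Edit freely: the scorer reloads this table at run time.
kind	key	value
init	.	4.09
loop_open	.	3.00
loop_extend	.	0.50
stack	AA/UU	-0.93
stack	AU/AU	-1.10
stack	AC/GU	-2.24
stack	AG/CU	-2.08
stack	UA/UA	-1.33
stack	UU/AA	-0.93
stack	UC/GA	-2.35
stack	UG/CA	-2.11
stack	CA/UG	-2.11
stack	CU/AG	-2.08
stack	CC/GG	-3.26
stack	CG/CG	-2.36
stack	GA/UC	-2.35
stack	GU/AC	-2.24
stack	GC/GC	-3.42
stack	GG/CC	-3.26
stack	GA/UU	-0.80
stack	GU/AU	-0.80
stack	GC/GU	-1.40
stack	GG/CU	-1.40
stack	GG/UU	0.50
stack	GU/GU	0.50
stack	UA/UG	-0.80
stack	UU/AG	-0.80
stack	UC/GG	-1.40
stack	UG/CG	-1.40
stack	UG/UG	0.50
stack	UU/GG	0.50
stack	AG/UU	-0.80
stack	AU/GU	-0.80
stack	UG/UA	-0.80
stack	UU/GA	-0.80
stack	CG/UG	-1.40
stack	CU/GG	-1.40
stack	GG/UC	-1.40
stack	GU/GC	-1.40
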