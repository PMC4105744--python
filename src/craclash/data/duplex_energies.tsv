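# Nearest-neighbor RNA-RNA duplex parameters (kcal/mol, 37 C).
# stack <pair_ij> <pair_i+1,j-1>: free energy of stacking step
# 5'-x_i x_i+1-3' / 3'-y_j y_j-1-5'; pair written as x-base then y-base.
param	key1	key2	value
stack	AU	AU	-0.93
stack	AU	UA	-1.10
stack	AU	GC	-2.08
stack	AU	CG	-2.24
stack	AU	GU	-0.55
stack	AU	UG	-1.36
stack	UA	AU	-1.33
stack	UA	UA	-0.93
stack	UA	GC	-2.11
stack	UA	CG	-2.35
stack	UA	GU	-1.27
stack	UA	UG	-1.00
stack	GC	AU	-2.35
stack	GC	UA	-2.24
stack	GC	GC	-3.26
stack	GC	CG	-3.42
stack	GC	GU	-1.53
stack	GC	UG	-2.51
stack	CG	AU	-2.11
stack	CG	UA	-2.08
stack	CG	GC	-2.36
stack	CG	CG	-3.26
stack	CG	GU	-1.41
stack	CG	UG	-2.11
stack	GU	AU	-1.00
stack	GU	UA	-1.36
stack	GU	GC	-2.11
stack	GU	CG	-2.51
stack	GU	GU	-0.50
stack	GU	UG	1.29
stack	UG	AU	-1.27
stack	UG	UA	-0.55
stack	UG	GC	-1.41
stack	UG	CG	-1.53
stack	UG	GU	-0.57
stack	UG	UG	-0.50
duplex_init	.	.	4.09
terminal_au	.	.	0.45
loop_base	.	.	2.00
loop_slope	.	.	0.50
max_loop	.	.	15
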