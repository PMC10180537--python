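# Reduced nearest-neighbor RNA energy parameters, 37 C, kcal/mol.
# kind=stack: key1=outer pair (i,j), key2=inner pair (i+1,j-1); the loader
#   expands the helix-direction symmetry stack[p][q] == stack[flip(q)][flip(p)].
# kind=hairpin|bulge|internal: key1=loop size (unpaired bases); sizes beyond
#   the table are extrapolated with a Jacobson-Stockmayer log term.
# kind=coef: scalar model coefficients.
kind	key1	key2	dG
stack	AU	AU	-0.93
stack	AU	UA	-1.10
stack	UA	AU	-1.33
stack	AU	CG	-2.24
stack	AU	GC	-2.08
stack	UA	CG	-2.35
stack	UA	GC	-2.11
stack	CG	CG	-3.26
stack	CG	GC	-2.36
stack	GC	CG	-3.42
stack	AU	GU	-1.36
stack	AU	UG	-0.55
stack	UA	GU	-1.27
stack	UA	UG	-1.00
stack	CG	GU	-2.11
stack	CG	UG	-1.41
stack	GC	GU	-2.51
stack	GC	UG	-1.53
stack	GU	GU	-0.50
stack	GU	UG	1.30
stack	UG	GU	0.30
hairpin	3	.	5.40
hairpin	4	.	5.60
hairpin	5	.	5.70
hairpin	6	.	5.40
hairpin	7	.	6.00
hairpin	8	.	5.50
hairpin	9	.	6.40
bulge	1	.	3.80
bulge	2	.	2.80
bulge	3	.	3.20
bulge	4	.	3.60
bulge	5	.	4.00
bulge	6	.	4.40
internal	2	.	1.50
internal	3	.	1.60
internal	4	.	1.70
internal	5	.	1.80
internal	6	.	2.00
coef	asym_per_base	.	0.50
coef	asym_max	.	3.00
coef	multiloop_close	.	3.40
coef	multiloop_branch	.	0.40
coef	multiloop_unpaired	.	0.00
coef	jacobson_stockmayer	.	1.08
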