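# locus: ND2
# N: D. lini=7	D. ohnishii=4	D. ogumai=2
position	region	kind	D. lini	D. ohnishii	D. ogumai
14	.	substitution	R	A	G
155	.	substitution	T	T	C
342	.	substitution	C	C	T
345	.	substitution	A	A	R
408	.	substitution	Y	C	T
411	.	substitution	A	A	G
434	.	substitution	G	G	A
487	.	substitution	S	S	G
543	.	substitution	T	T	C
552	.	substitution	A	R	A
667	.	substitution	W	A	A
669	.	substitution	W	A	A
747	.	substitution	R	G	G
781	.	substitution	T	T	C
796	.	substitution	C	C	T
829	.	substitution	M	A	A
895	.	substitution	C	C	T
900	.	substitution	T	T	C
934	.	substitution	C	C	T
954	.	substitution	C	C	T
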