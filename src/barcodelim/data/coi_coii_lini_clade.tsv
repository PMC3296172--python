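# locus: COI-COII
# N: D. lini=7	D. ohnishii=4	D. ogumai=2
position	region	kind	D. lini	D. ohnishii	D. ogumai
1407	COI	substitution	C	C	Y
1485	COI	substitution	Y	C	T
1503	COI	substitution	T	T	C
69	COII	substitution	T	T	C
72	COII	substitution	C	C	T
231	COII	substitution	C	C	T
232	COII	substitution	T	Y	T
234	COII	substitution	R	A	A
399	COII	substitution	Y	T	T
435	COII	substitution	W	A	A
486	COII	substitution	A	A	G
570	COII	substitution	R	A	A
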