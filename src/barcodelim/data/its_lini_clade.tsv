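# locus: ITS
# N: D. lini=6	D. ohnishii=2	D. ogumai=2
position	region	kind	D. lini	D. ohnishii	D. ogumai
16	ITS1	substitution	G	G	A
307	ITS2	substitution	T	T	G
312	ITS2	indel	present:GTCAATAATAAAAT	-/present:GTCAATAATAAAAT	present:GTCAATAATAAAAT
326	ITS2	indel	-	-	present:T
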