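haplotype	ycf6-psbM:s1	ycf6-psbM:i1	trnT-trnL:i1	trnT-trnL:i2	rps16:i1	rps16:s1	atpI-atpH:s1	atpI-atpH:s2
A	T	-	-	-	-	G	T	A
B	T	-	TAGAACCG	-	-	G	T	A
C	T	-	-	-	TGTCATG	A	T	A
D	T	TATAT	-	-	-	G	T	C
E	T	-	-	-	-	G	T	C
F	G	-	-	-	-	G	T	A
G	T	-	TAGAACCG	TATTTG	-	G	T	A
H	T	TATAT	-	-	-	G	G	C
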