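# Nucleotide substitution scores (gap symbol '-').
nt	A	C	G	U	-
A	2	-1	-1	-1	-2
C	-1	2	-1	-1	-2
G	-1	-1	2	-1	-2
U	-1	-1	-1	2	-2
-	-2	-2	-2	-2	0
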