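# Synthetic interaction-frequency table for annotation-conflict arbitration.
# Counts are plausible relative magnitudes for (nt5, nt3, LW-type)
# combinations in ribosomal-scale RNA structure sets; they are NOT derived
# from a structure survey.  Supply your own TSV to replace it.
nt5	nt3	lw_type	count
G	C	cis-W/W	52000
C	G	cis-W/W	52000
A	U	cis-W/W	31000
U	A	cis-W/W	31000
G	U	cis-W/W	9000
U	G	cis-W/W	9000
G	A	trans-H/S	4200
A	G	trans-S/H	4200
A	A	trans-H/S	900
G	G	trans-H/S	600
U	A	trans-W/H	1300
A	U	trans-H/W	1300
G	A	trans-S/S	750
A	G	trans-S/S	750
A	A	trans-S/S	400
U	U	trans-W/W	500
A	U	trans-W/W	450
G	U	trans-W/H	350
C	A	cis-H/S	300
A	C	cis-S/H	300
G	A	cis-H/S	280
A	G	cis-S/H	280
U	G	trans-S/H	260
G	U	trans-H/S	260
A	A	trans-H/H	240
U	U	cis-W/H	150
G	G	cis-W/H	120
A	C	trans-W/W	100
C	C	cis-W/W	80
A	G	cis-W/W	340
G	A	cis-W/W	340
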