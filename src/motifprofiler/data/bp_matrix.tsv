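# Base-pair substitution scores over the 18 Leontis-Westhof classes.
# Isostericity-patterned: identical class 5, edge-swapped class 2.5,
# shared-edge same orientation 1, same orientation otherwise -1,
# orientation mismatch -2.
type	cis-W/W	cis-W/H	cis-W/S	cis-H/W	cis-H/H	cis-H/S	cis-S/W	cis-S/H	cis-S/S	trans-W/W	trans-W/H	trans-W/S	trans-H/W	trans-H/H	trans-H/S	trans-S/W	trans-S/H	trans-S/S
cis-W/W	5	1	1	1	-1	-1	1	-1	-1	-2	-2	-2	-2	-2	-2	-2	-2	-2
cis-W/H	1	5	1	2.5	1	-1	-1	1	-1	-2	-2	-2	-2	-2	-2	-2	-2	-2
cis-W/S	1	1	5	-1	-1	1	2.5	-1	1	-2	-2	-2	-2	-2	-2	-2	-2	-2
cis-H/W	1	2.5	-1	5	1	1	1	-1	-1	-2	-2	-2	-2	-2	-2	-2	-2	-2
cis-H/H	-1	1	-1	1	5	1	-1	1	-1	-2	-2	-2	-2	-2	-2	-2	-2	-2
cis-H/S	-1	-1	1	1	1	5	-1	2.5	1	-2	-2	-2	-2	-2	-2	-2	-2	-2
cis-S/W	1	-1	2.5	1	-1	-1	5	1	1	-2	-2	-2	-2	-2	-2	-2	-2	-2
cis-S/H	-1	1	-1	-1	1	2.5	1	5	1	-2	-2	-2	-2	-2	-2	-2	-2	-2
cis-S/S	-1	-1	1	-1	-1	1	1	1	5	-2	-2	-2	-2	-2	-2	-2	-2	-2
trans-W/W	-2	-2	-2	-2	-2	-2	-2	-2	-2	5	1	1	1	-1	-1	1	-1	-1
trans-W/H	-2	-2	-2	-2	-2	-2	-2	-2	-2	1	5	1	2.5	1	-1	-1	1	-1
trans-W/S	-2	-2	-2	-2	-2	-2	-2	-2	-2	1	1	5	-1	-1	1	2.5	-1	1
trans-H/W	-2	-2	-2	-2	-2	-2	-2	-2	-2	1	2.5	-1	5	1	1	1	-1	-1
trans-H/H	-2	-2	-2	-2	-2	-2	-2	-2	-2	-1	1	-1	1	5	1	-1	1	-1
trans-H/S	-2	-2	-2	-2	-2	-2	-2	-2	-2	-1	-1	1	1	1	5	-1	2.5	1
trans-S/W	-2	-2	-2	-2	-2	-2	-2	-2	-2	1	-1	2.5	1	-1	-1	5	1	1
trans-S/H	-2	-2	-2	-2	-2	-2	-2	-2	-2	-1	1	-1	-1	1	2.5	1	5	1
trans-S/S	-2	-2	-2	-2	-2	-2	-2	-2	-2	-1	-1	1	-1	-1	1	1	1	5
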