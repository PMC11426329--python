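# Stacking-category substitution scores.
category	upward	downward	inward	outward
upward	3	0.5	-1	-1
downward	0.5	3	-1	-1
inward	-1	-1	3	0.5
outward	-1	-1	0.5	3
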