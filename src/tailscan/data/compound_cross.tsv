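genotype	no_tail	short_tail	kinked_tail	long_tail	breeding_type	runt_death
dexon6/insRCS2	7	0	0	0	insRCS2/+_x_dexon6/+	2
dexon6/+	0	0	1	10	insRCS2/+_x_dexon6/+	0
insRCS2/+_or_+/+	0	0	0	12	insRCS2/+_x_dexon6/+	0
dexon6/insRCS2	12	0	0	0	insRCS2/insRCS2_x_dexon6/+	4
insRCS2/+	0	0	0	30	insRCS2/insRCS2_x_dexon6/+	0
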