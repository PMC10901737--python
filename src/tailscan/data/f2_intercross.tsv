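genotype	no_tail	short_tail	kinked_tail	long_tail
dexon6/dexon6	0	0	0	0
dexon6/+	4	9	8	42
+/+	0	0	0	35
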