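name	recognition	cut_offset
BamHI	GGATCC	1
EcoRI	GAATTC	1
PstI	CTGCAG	5
RsaI	GTAC	2
SalI	GTCGAC	1
SacI	GAGCTC	5
KpnI	GGTACC	5
XhoI	CTCGAG	1
Sau3AI	GATC	0
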