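type	enzyme	fragments_bp
I	PstI	279
I	RsaI	124,54,101
I	SalI	279
II	PstI	279
II	RsaI	279
II	SalI	279
III	PstI	279
III	RsaI	124,54,101
III	SalI	201,78
IV	PstI	168,111
IV	RsaI	279
IV	SalI	279
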