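name	length_bp	gc_percent	gc_skew	at_skew	at_rich_length_bp	at_rich_gc_percent	accession
WBPHTA	16613	23.8	-0.14163	0.094715	2219	17.5	MK907866
WBPHHN	16612	23.8	-0.14055	0.092920	2223	17.5	NC_021417
WBPHYN	16654	23.8	-0.14070	0.094262	2264	17.7	KC512915
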