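doc_id	sent_index	char_start	char_end	surface	etype	norm_id
d1	0	0	4	IL-6	gene	IL6
d2	0	4	15	BCG vaccine	vaccine_specific	VO:0000201
d3	0	4	11	vaccine	vaccine_general	vaccine
d5	0	0	5	MAPK1	gene	MAPK1
d5	0	12	16	ERK1	gene	MAPK3
d7	0	0	2	AS	gene	AS
d7	0	20	22	T4	gene	CD4
d7	0	27	31	BSF2	gene	IL6
d8	0	0	13	Interleukin 6	gene	IL6
d8	0	18	27	TNF-alpha	gene	TNF
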