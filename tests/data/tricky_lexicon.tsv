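symbol	name	synonyms
IL6	interleukin 6	IL-6|BSF2
TNF	tumor necrosis factor	TNF-alpha
MAPK1	mitogen-activated protein kinase 1	ERK2|ERK
MAPK3	mitogen-activated protein kinase 3	ERK1|ERK
CD4	CD4 molecule	T4
AS	argininosuccinate synthase-like short symbol	
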