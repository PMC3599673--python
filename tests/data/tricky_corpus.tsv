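doc_id	title	abstract
d1		IL-6 induces fever.
d2		The BCG vaccine reduced fever.
d3		The vaccine was safe.
d4		ERK was phosphorylated.
d5		MAPK1 binds ERK1.
d6		As expected, as controls worked.
d7		AS levels rose with T4 and BSF2.
d8		Interleukin 6 and TNF-alpha interact.
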