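format-version: 1.2
ontology: synthetic-tricky-vaccines

[Term]
id: VO:0000001
name: vaccine

[Term]
id: VO:0000010
name: bacterial vaccine
is_a: VO:0000001 ! vaccine

[Term]
id: VO:0000201
name: BCG vaccine
synonym: "BCG" EXACT []
is_a: VO:0000010 ! bacterial vaccine

[Term]
id: VO:0000202
name: MMR vaccine
is_a: VO:0000001 ! vaccine
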