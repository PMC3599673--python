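# Interaction-keyword stems (one per line). Matched case-insensitively at
# token boundaries after light stemming, so "activates", "activated" and
# "activating" all hit "activate". User-replaceable via --keywords.
bind
activate
induce
inhibit
suppress
regulate
interact
stimulate
attach
ligate
associate
modulate
mediate
trigger
block
enhance
promote
repress
upregulate
downregulate
phosphorylate
dephosphorylate
acetylate
methylate
ubiquitinate
cleave
degrade
stabilize
destabilize
recruit
release
secrete
express
coexpress
transactivate
silence
antagonize
agonize
potentiate
attenuate
sensitize
desensitize
catalyze
oxidize
reduce
transport
translocate
sequester
dimerize
heterodimerize
oligomerize
complex
crosslink
target
neutralize
elicit
augment
abolish
accelerate
amplify
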