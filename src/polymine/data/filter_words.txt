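# Default system filter words: verbs and phrases that signify a strong
# association between two co-mentioned entities. One normalized term per
# line; multi-word phrases are matched as contiguous token runs.
activates
activated
activation
aggravates
alleviates
ameliorates
antagonizes
associated
associates
association
attenuates
binds
blocks
catalyzes
catalyzed
causes
caused
causative
contributes
controls
converts
correlates
correlated
correlation
decreases
decreased
degrades
deregulates
diminishes
disrupts
downregulates
downregulated
drives
elevates
elevated
elicits
encodes
enhances
exacerbates
impairs
implicated
implicates
increases
increased
induces
induced
induction
influences
inhibits
inhibited
inhibition
inhibitor
interacts
interaction
involved
involves
linked
links
mediates
mediated
metabolizes
modulates
modulated
phosphorylates
potentiates
predicts
predisposes
prevents
promotes
protects
reduces
reduced
regulates
regulated
regulation
represses
responds
restores
stabilizes
stimulates
stimulated
suppresses
suppressed
targets
transactivates
transcribes
transports
triggers
triggered
upregulates
upregulated
worsens
risk factor for
increases the risk of
raises the risk of
gives rise to
leads to
results in
plays a role in
is required for
predisposes to
susceptibility to
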