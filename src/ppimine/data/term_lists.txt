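# Trigger-term lists for PPIm document triage and relation extraction.
# Entries are stemmed and deduplicated at load time; categories must be
# pairwise disjoint after stemming.

[strong_mutation]
mutation
mutant
mutants
variant
delete
insertion
substitution
-/-
+/-
polymorphism
SNP
lesion
mutagenesis
mutagenic
mutagenetic
deleterious

[weak_mutation]
change
exchange
damage
remove
replace
disorder
deficiency
virulence
truncation

[interaction]
interact
complex
bound
bind
regulate
kinase
acetylation
phosphorylation
associate
dissociate
ubiquitination
methylation
glycosylation
sumoylation
dimerization
oligomerization
cleavage
recruit
coimmunoprecipitation
crosslink
tether
scaffold
ligand
receptor
substrate
heterodimer
homodimer
dock
affinity
coprecipitate

[degree]
increase
decrease
degrade
strengthen
enhance
reduce
impair
abolish
disrupt
diminish
attenuate
weaken
augment
promote
prevent
block
stimulate
accelerate
elevate
abrogate
restore
modulate
alter
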