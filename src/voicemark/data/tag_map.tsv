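a	Adjectives
c	Conjunctions
d	Adverbs
n	Nouns
v	Verbs
q	Measure Words
p	Prepositions
r	Pronouns
t	Time
m	Numerals
u	Particles
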