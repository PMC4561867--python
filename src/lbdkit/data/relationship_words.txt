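# Seed relationship-word list: verbs and nominalizations whose presence
# near a candidate pair signals an asserted relation.  Matched
# case-insensitively against lemmas; users may supply a larger list.
activate
activation
affect
alter
associate
association
attenuate
augment
block
cause
change
contribute
control
decrease
deplete
diminish
disrupt
downregulate
elevate
elicit
enhance
exacerbate
impair
improve
increase
induce
induction
inhibit
inhibition
initiate
interact
interaction
involve
involved
lower
mediate
modify
modulate
potentiate
prevent
produce
promote
protect
raise
reduce
reduction
regulate
regulation
relieve
respond
restore
result
reverse
stimulate
stimulation
suppress
suppression
treat
treatment
trigger
upregulate
worsen
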