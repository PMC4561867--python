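# Negation cues: their presence alongside a relationship word often
# reverses or voids the asserted relation.
absence
absent
cannot
fail
failure
lack
neither
never
no
none
nor
not
unable
unlikely
without
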