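# Default negation words: a sentence containing any of these (as a token
# or a contiguous token bigram) is excluded from the evidence.
not
no
never
neither
nor
without
cannot
lacks
lacking
absence
absent
unrelated
unlikely
unaffected
insignificant
nonsignificant
fails to
failed to
no evidence
not associated
no association
cannot exclude
rather than
instead of
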