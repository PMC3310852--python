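# Chapter-level mappings from the ICF Activities and Participation
# component to SUMO: the chapters for which a chapter-wide SUMO
# superclass is asserted.
source_code	target_concept	match_kind	note
d2	IntentionalProcess	broader	generic classification of tasks by complexity and other features
d4	Motion	broader	target is not an IntentionalProcess in SUMO
d5	IntentionalProcess	broader
d6	IntentionalProcess	broader
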