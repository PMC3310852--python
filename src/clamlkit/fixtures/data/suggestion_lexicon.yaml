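# Editable cue lexicon for rule-based relationship suggestions.
# Phrases are matched case-insensitively on word boundaries in the child
# concept's preferred title.  Precedence when several relations fire:
# SubProcess > Agent > Patient > Instrument > Complexity.
# Suggestions are advisory; curated annotation tables always win.
SubProcess:
  - starting
  - sustaining
  - ending
  - completing
  - initiating
  - terminating
  - preparing
Agent:
  - with one person
  - with many people
  - one person
  - many people
  - alone
  - in a group
  - as a member of a group
Patient: []   # the object of an activity has no reliable lexical cue
Instrument:
  - using
  - by means of
  - with devices
  - device
  - machine
Complexity:
  - simple
  - complex
  - single
  - multiple
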