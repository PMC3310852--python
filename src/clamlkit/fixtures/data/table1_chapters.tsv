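# The nine chapters of the ICF Activities and Participation component.
code	title
d1	Learning and applying knowledge
d2	General tasks and demands
d3	Communication
d4	Mobility
d5	Self-care
d6	Domestic life
d7	Interpersonal interactions and relationships
d8	Major life areas
d9	Community, social and civic life
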