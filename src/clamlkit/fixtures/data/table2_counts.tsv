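# Relationship usage per chapter of the ICF Activities and Participation
# component.  level "top" = chapter-to-category links (blocks transparent),
# "lower" = category-to-subcategory and deeper.  Zero cells are omitted.
# Derived column sums: top 98 edges (88 Subsumption), lower 175 edges
# (103 Subsumption).
chapter	level	relation	count
d1	top	Subsumption	19
d1	lower	Complexity	4
d2	top	Subsumption	1
d2	top	SubProcess	2
d2	lower	Subsumption	1
d2	lower	SubProcess	4
d2	lower	Agent	4
d2	lower	Patient	3
d2	lower	Complexity	2
d3	top	Subsumption	14
d3	lower	SubProcess	3
d3	lower	Agent	4
d3	lower	Patient	8
d3	lower	Instrument	1
d4	top	Subsumption	17
d4	lower	Subsumption	33
d4	lower	Patient	6
d4	lower	Instrument	4
d4	lower	Complexity	7
d5	top	Subsumption	7
d5	lower	Subsumption	17
d5	lower	Patient	2
d6	top	Subsumption	9
d6	lower	Subsumption	24
d6	lower	Complexity	2
d7	top	Subsumption	3
d7	top	Patient	4
d7	top	Complexity	2
d7	lower	Subsumption	12
d7	lower	SubProcess	2
d7	lower	Patient	12
d7	lower	Instrument	1
d8	top	Subsumption	13
d8	top	Complexity	2
d8	lower	Subsumption	5
d8	lower	SubProcess	3
d9	top	Subsumption	5
d9	lower	Subsumption	11
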