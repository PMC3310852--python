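# Block-, category- and subcategory-level mappings from the ICF
# Activities and Participation component to SUMO.
source_code	target_concept	match_kind	note
d160-d179	IntentionalPsychologicalProcess	broader	applying knowledge; only some members have SUMO counterparts
d310-d329	Interpreting	broader	receiving side of communication; a superclass over generic content would fit better
d330-d349	ContentDevelopment	partial	producing side of communication; mapped with some doubts
d350-d369	Communication	broader	conversation and use of communication devices
d170	Writing	equivalent
d172	Calculating	equivalent
d540	Dressing	equivalent
d550	Eating	equivalent
d560	Drinking	equivalent
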