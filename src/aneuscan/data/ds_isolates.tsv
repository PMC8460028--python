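isolate	candidate_mutation	mutation_class	monosomy	trisomy	tetrasomy	growth
DS2	none	none		8,11,12,14,15	13	normal
DS5	none	none		14	8	normal
DS6	none	none		3,5,8,11,12,14		normal
DS7	REG1-Y638Stop	nonsense		8		normal
DS14	none	none	1		8	normal
DS18	none	none		5,9,10,11,13,14,16	3,8	normal
DS15	REG1-Q332Stop	nonsense				normal
DS16	GAL83-S224R	missense				normal
DS21	SNF4-N177S	missense				normal
DS8	none	none	4			slow growth
DS9	HXT367-dup117kb	duplication	4	2		slow growth
DS10	none	none	4			slow growth
DS11	none	none	4			slow growth
DS12	none	none	4			slow growth
DS13	none	none	4			slow growth
DS19	none	none	4			slow growth
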