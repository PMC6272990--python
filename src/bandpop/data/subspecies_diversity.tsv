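subspecies	na	ne	he	shannon
santai	1.898	1.409	0.257	0.401
smithii	1.871	1.372	0.235	0.370
woronowii	1.807	1.344	0.217	0.340
lusitanica	1.471	1.213	0.135	0.211
himalayensis	1.556	1.255	0.159	0.248
glomerata	1.536	1.264	0.162	0.251
lobata	1.881	1.368	0.232	0.366
hispanica	1.993	1.420	0.269	0.425
marina	1.519	1.307	0.184	0.276
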