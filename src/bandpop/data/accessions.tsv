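accession	subspecies	country	range	climate
PI237605	santai	Algeria	Unknown	Mediterranean
PI368880	santai	Algeria	Unknown	Mediterranean
PI441034	smithii	United Kingdom	Africa	Subtropical
PI237607	smithii	Spain	Africa	Subtropical
PI538922	woronowii	Russia	Asia-Temperate	Mediterranean
PI237610	woronowii	Iran	Asia-Temperate	Mediterranean
PI237602	lusitanica	Portugal	Europe	Mediterranean
PI295271	himalayensis	India	Asia-Tropical	Temperate
PI538920	glomerata	Russia	Unknown	Temperate
PI316209	lobata	Bulgaria	Europe	Temperate
PI372621	lobata	Germany	Europe	Temperate
PI283242	lobata	Germany	Europe	Temperate
PI231517	hispanica	Morocco	Africa	Mediterranean
PI265568	hispanica	Spain	Europe-Africa	Mediterranean
PI265567	hispanica	France	Europe	Mediterranean
PI224599	hispanica	Israel	Unknown	Mediterranean
PI277836	hispanica	Turkey	Asia-Temperate	Mediterranean
PI231550	hispanica	Greece	Europe	Mediterranean
PI231541	hispanica	Portugal	Europe	Mediterranean
PI577065	marina	Portugal	Europe	Mediterranean
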