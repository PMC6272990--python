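analysis	stratum	sum_sq	variance_component	df
accessions	among	2132.571	10.892	19
accessions	within	8661.510	46.072	176
hispanica_countries	among	1384.837	11.434	6
hispanica_countries	within	6139.533	94.454	63
lobata_countries	among	165.050	8.970	2
lobata_countries	within	1272.750	45.455	27
smithii_countries	among	144.800	10.340	2
smithii_countries	within	745.200	41.400	17
woronowii_countries	among	141.300	10.508	2
woronowii_countries	within	652.000	36.222	17
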