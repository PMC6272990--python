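primer	system	tnb	npb	pic
FOG215	SSR	11	11	0.916
FOG238	SSR	9	9	0.768
FOG258	SSR	13	13	0.909
FOG296	SSR	6	6	0.869
FOG362	SSR	10	10	0.962
FOG402	SSR	8	8	0.861
FOG514	SSR	11	11	0.959
FOG515	SSR	10	10	0.940
FOG537	SSR	7	7	0.938
FOG591	SSR	10	10	0.916
FOG634	SSR	9	9	0.928
FOG655	SSR	8	8	0.910
FOG707	SSR	8	8	0.956
FOG112	SSR	10	10	0.905
FOG393	SSR	8	8	0.948
FOG455	SSR	10	10	0.872
FOG598	SSR	8	8	0.920
FOG624	SSR	9	9	0.871
FOG824	SSR	9	9	0.875
FOG831	SSR	13	13	0.952
DGSSR14primer12	SSR	9	9	0.914
IT-ISJ01F03R	IT-ISJ	8	8	0.616
IT-ISJ01F04R	IT-ISJ	8	8	0.874
IT-ISJ01F05R	IT-ISJ	5	5	0.957
IT-ISJ01F08R	IT-ISJ	6	6	0.710
IT-ISJ03F41R	IT-ISJ	9	9	0.833
IT-ISJ03F47R	IT-ISJ	7	7	0.741
IT-ISJ03F59R	IT-ISJ	10	10	0.728
IT-ISJ04F04R	IT-ISJ	6	6	0.626
IT-ISJ05F20R	IT-ISJ	7	7	0.835
IT-ISJ05F36R	IT-ISJ	3	3	0.924
IT-ISJ06F50R	IT-ISJ	3	3	0.911
IT-ISJ07F05R	IT-ISJ	7	7	0.814
IT-ISJ07F11R	IT-ISJ	7	7	0.727
IT-ISJ07F12R	IT-ISJ	8	8	0.852
IT-ISJ07F15R	IT-ISJ	5	5	0.545
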