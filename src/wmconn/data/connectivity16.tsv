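name	area	hemisphere	n_subrois	role	inferred
LSTC	STC	left	34	both	0
RSTC	STC	right	29	both	0
LMFG	MFG	left	43	both	0
RMFG	MFG	right	50	both	0
LIFG	IFG	left	23	both	0
RIFG	IFG	right	14	both	0
LPreC	PreC	left	30	both	1
RPreC	PreC	right	30	both	1
LSMG	SMG	left	34	both	0
RSMG	SMG	right	32	both	0
LAG	AG	left	33	both	0
RAG	AG	right	37	both	0
LSPL	SPL	left	76	both	0
RSPL	SPL	right	80	both	0
LOC	OC	left	62	both	0
ROC	OC	right	51	both	0
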