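sample_id	marker	detected
CxL_24_r1	ACT11	1
CxL_24_r1	WOX9	1
CxL_24_r1	TT10	0
CxL_24_r1	AT5G42530	0
CxL_24_r1	FWA	0
CxL_24_r1	AGL46	0
CxL_24_r1	AGL62	0
LxC_24_r1	ACT11	1
LxC_24_r1	WOX9	1
LxC_24_r1	TT10	0
LxC_24_r1	AT5G42530	0
LxC_24_r1	FWA	0
LxC_24_r1	AGL46	0
LxC_24_r1	AGL62	0
CxL_24_6x	ACT11	1
CxL_24_6x	WOX9	1
CxL_24_6x	TT10	0
CxL_24_6x	AT5G42530	0
CxL_24_6x	FWA	0
CxL_24_6x	AGL46	0
CxL_24_6x	AGL62	0
LxC_24_6x	ACT11	0
LxC_24_6x	WOX9	0
LxC_24_6x	TT10	0
LxC_24_6x	AT5G42530	0
LxC_24_6x	FWA	0
LxC_24_6x	AGL46	0
LxC_24_6x	AGL62	0
SCE	ACT11	1
SCE	WOX9	0
SCE	TT10	1
SCE	AT5G42530	1
SCE	FWA	1
SCE	AGL46	1
SCE	AGL62	1
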