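id	group	lesion_side	fma_pre	fma_post
BCI01	BCI-FES	R	3	5
BCI02	BCI-FES	R	1	5
BCI03	BCI-FES	L	25	28
BCI04	BCI-FES	R	12	12
BCI05	BCI-FES	R	5	7
BCI06	BCI-FES	R	4	6
BCI07	BCI-FES	R	32	35
BCI08	BCI-FES	R	33	33
BCI09	BCI-FES	L	52	53
BCI10	BCI-FES	R	30	30
BCI11	BCI-FES	R	30	30
BCI12	BCI-FES	R	3	5
FES01	FES	L	0	0
FES02	FES	R	58	58
FES03	FES	R	45	45
FES04	FES	R	27	25
FES05	FES	R	20	20
FES06	FES	L	44	43
FES07	FES	L	2	2
FES08	FES	L	6	6
FES09	FES	R	56	59
FES10	FES	L	31	30
FES11	FES	L	24	24
FES12	FES	L	30	30
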