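gene	trait	module	f	K	GS
TP53	grade	yellow	954	0.40	0.31
AURKB	grade	yellow	885	0.41	0.37
BUB1	grade	yellow	768	0.43	0.42
CENPA	grade	yellow	764	0.44	0.42
AURKB	type	yellow	995	0.41	0.35
PRC1	type	yellow	893	0.34	0.33
CDC6	type	yellow	849	0.26	0.24
E2F2	type	yellow	776	0.31	0.22
KIF20A	type	yellow	760	0.46	0.21
BUB1	stage	yellow	768	0.43	0.42
FEN1	stage	yellow	764	0.27	0.32
KIF23	stage	yellow	763	0.34	0.27
CDC20	stage	yellow	762	0.37	0.32
PRC1	stage	yellow	760	0.34	0.27
IDH3G	stage	blue	934	0.36	0.49
NDUFV2	stage	blue	873	0.35	0.42
ATP5B	stage	blue	769	0.52	0.49
PSMB3	stage	blue	762	0.41	0.47
PSMB7	stage	blue	760	0.32	0.42
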