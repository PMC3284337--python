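family	codon_t	codon_c	n_t_pgamma	n_c_pgamma	n_t_pepsilon	n_c_pepsilon
Phe	TTT	TTC	35134	34354	37411	32448
Val	GTT	GTC	29941	19977	30325	18937
Ser	TCT	TCC	34498	19030	36153	18412
Pro	CCT	CCC	24501	12414	25360	11999
Thr	ACT	ACC	25044	17961	26245	16932
Ala	GCT	GCC	30768	19557	31479	18060
His	CAT	CAC	20343	14426	20787	13818
Asn	AAT	AAC	48995	42467	51063	41316
Asp	GAT	GAC	55556	41307	56476	39959
Cys	TGT	TGC	10196	8105	10161	8250
Ser	AGT	AGC	21219	20817	21365	20682
Gly	GGT	GGC	30801	16937	29869	16931
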