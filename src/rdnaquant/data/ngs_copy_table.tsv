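species	genome_mb	total_reads	mapped_reads	gp_percent_published	gp_mb_published	copies_published	ref_len_mb
Physcomitrella patens	480	131650374	528177	0.40	1.93	650	0.003
Marchantia polymorpha	287	141348695	3486319	2.47	7.08	2400	0.003
Funaria hygrometrica	394			3.51	13.8	1200	0.0112
Nicotiana tomentosiformis	2500	7479035	19115	0.26	6.39	1800	0.003
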