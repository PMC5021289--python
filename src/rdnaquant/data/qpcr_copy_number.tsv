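species	copies_per_1c	sd
Marchantia polymorpha	1263	126
Conocephalum conicum	670	161
Lunularia cruciata	693	118
Pellia endiviifolia	1970	315
Porella platyphylla	1169	245
Plagiochila porelloides	2003	361
Bazzania trilobata	666	73
Atrichum undulatum	1169	129
Polytrichum piliferum	2458	467
Encalypta streptocarpa	1897	304
Physcomitrella patens	903	45
Fissidens dubius	1238	173
Syntrichia ruralis	1595	175
Tortella tortuosa	704	85
Bryum capillare	667	167
Plagiomnium undulatum	2070	248
Aulacomnium palustre	735	147
Isothecium alopecuroides	659	86
Homalothecium lutescens	1678	252
Hylocomium splendens	1007	171
Hypnum cupressiforme	1359	285
Neckera complanata	858	206
Neckera crispa	678	142
Thamnobryum alopecurum	696	139
Thuidium delicatulum	434	87
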