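otu	n_samples	species	larvae	larvae_sequenced	cad_units	coi_units	cad_ptp	cad_gmyc	coi_ptp	coi_gmyc	recip_mono	printed_n_criteria
H. acharai	4	H. acharai	yes	yes	1/1	1/1	yes	yes	yes	yes	yes	5
H. anomala	6	H. anomala	yes	yes	1/1	4/3	yes	yes	no	yes	yes	4
H. auricularis	2	H. auricularis	no	no	1/1	2/1	ne	ne	ne	ne	ne
H. biansata	2	H. biansata	no	no	no data	1/1	ne	ne	ne	ne	ne
H. diehli	1	H. diehli	no	no	1/1	1/1	ne	ne	ne	ne	ne
H. digitata	34	H. digitata	yes	yes	2/1	2/2	yes	yes	no	no	yes	3
H. eos	2	H. eos	no	no	no data	1/1	ne	ne	ne	ne	ne
excisa-complex	31	H. excisa;H. placida;H. maitreya	yes	yes	1/1	5/2	no	no	no	no	no	0
H. gigantea	2	H. gigantea	no	no	no data	1/1	ne	ne	ne	ne	ne
H. gregoryi	77	H. gregoryi	yes	yes	1/1	1/1	yes	yes	yes	yes	yes	5
H. gyamo	1	H. gyamo	no	no	1/1	1/1	ne	ne	ne	ne	ne
H. horai	5	H. horai	no	no	1/1	1/1	ne	ne	ne	ne	yes
japonica-complex	8	H. japonica;H. sp. n. 1529	yes	no	2/1	4/3	ne	ne	ne	ne	no
H. kuldschensis	2	H. kuldschensis	no	no	1/1	1/1	ne	ne	ne	ne	yes
H. lanceolata	4	H. lanceolata	no	no	1/1	1/1	ne	ne	ne	ne	yes
H. lepcha	5	H. lepcha	no	no	1/1	2/2	ne	ne	ne	ne	yes
H. lua	5	H. lua	no	no	no data	2/1	ne	ne	ne	ne	ne
martynovi-complex	30	H. martynovi;H. epikur	yes	yes	martynovi-clade	1/1	no	no	no	no	no	0
H. navasi	4	H. navasi	no	no	1/1	4/4	ne	ne	ne	ne	ne
H. phryganea	4	H. phryganea	yes	yes	1/1	2/2	yes	yes	yes	yes	yes	5
platon-complex	27	H. platon	yes	yes	1/1	4/3	no	no	no	no	yes	1
H. sp. 1196 (L)	17		yes	yes	1/1	2/1	ne	ne	ne	ne	yes
H. sp. 1254 (L)	4		yes	yes	1/1	no data	ne	ne	ne	ne	ne
H. sp. 1338 (L)	1		yes	yes	1/1	1/1	ne	ne	ne	ne	ne
H. sylvicola	33	H. sylvicola	yes	yes	1/1	6/3	yes	yes	no	yes	yes	5
H. tibetana	58	H. tibetana	yes	yes	1/1	2/2	yes	yes	yes	yes	yes	5
H. todma	4	H. todma	no	no	1/1	no data	ne	ne	ne	ne	ne
triloba-complex	67	H. triloba;H. hageni;H. maculipennis;H. malenanda;H. efiel;H. yatrawalla	yes	yes	2/2	5/3	no	no	no	no	no	0
H. yongma	1	H. yongma	no	no	1/1	1/1	ne	ne	ne	ne	ne
H. 677	41	H. 677	yes	yes	1/1	1/1	yes	yes	yes	yes	yes	5
H. 683	8	H. 683	no	no	martynovi-clade	1/1	ne	ne	ne	ne	yes
H. 685	34	H. 685	yes	yes	martynovi-clade	1/1	no	no	yes	yes	yes	3
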