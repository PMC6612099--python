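TargetID	Chr	Position	Gene_Name	Gene_Region	Island_Relation	beta_sens	beta_res	delta_printed
cg08757148	1	24513722	IL28RA;IL28RA;IL28RA	1stExon;1stExon;1stExon	Island	0.11	0.67	0.56
cg03470088	1	24513939	IL28RA;IL28RA;IL28RA	TSS200;TSS200;TSS200	Island	0.05	0.79	0.75
cg26558485	1	47489282	CYP4X1;CYP4X1	1stExon;5'UTR	Island	0.14	0.69	0.54
cg06816106	2	29033352	SPDYA;SPDYA	TSS1500;TSS1500	Island	0.18	0.64	0.46
cg14798656	2	97760745	FAHD2B	TSS200	Island	0.17	0.62	0.45
cg25999267	3	39424992	SLC25A38;SLC25A38	1stExon;5'UTR	Island	0.19	0.75	0.56
cg17264618	3	40429014	ENTPD3	5'UTR	Island	0.14	0.61	0.46
cg09363539	3	124931746	SLC12A8	TSS200	Island	0.01	0.82	0.81
cg15860013	3	138327718	FAIM;FAIM;FAIM;FAIM;FAIM;FAIM;FAIM	5'UTR;TSS200;1stExon;5'UTR;1stExon;5'UTR;1stExon	Island	0.18	0.68	0.50
cg20841906	3	160822911	B3GALNT1;B3GALNT1;B3GALNT1;B3GALNT1;B3GALNT1	5'UTR;5'UTR;5'UTR;5'UTR;TSS1500	Island	0.06	0.70	0.64
cg20986370	4	57976171	IGFBP7	1stExon	Island	0.19	0.69	0.49
cg19031658	4	74964856	CXCL2;CXCL2	1stExon;5'UTR	Island	0.05	0.89	0.85
cg22847221	4	74964920	CXCL2;CXCL2	1stExon;5'UTR	Island	0.13	0.61	0.48
cg00630212	4	74965135	CXCL2	TSS200	Island	0.16	0.65	0.49
cg18804985	4	74965226	CXCL2	TSS1500	Island	0.18	0.96	0.78
cg01429321	5	121413797	LOX;LOX	5'UTR;1stExon	Island	0.10	0.62	0.52
cg21034676	5	135364552	TGFBI	TSS200	Island	0.11	0.61	0.51
cg14120129	5	135364575	TGFBI	TSS200	Island	0.06	0.61	0.55
cg09873933	5	135364580	TGFBI	TSS200	Island	0.09	0.63	0.54
cg07151644	6	31649089	LY6G5C	TSS1500	Island	0.16	0.60	0.44
cg07753583	7	150020206	LRRC61;ACTR3C;LRRC61	TSS200;5'UTR;TSS200	Island	0.17	0.86	0.69
cg10348193	7	150020240	LRRC61;ACTR3C;LRRC61	TSS200;5'UTR;TSS200	Island	0.15	0.97	0.82
cg11026333	7	150020269	LRRC61;ACTR3C;LRRC61	TSS200;5'UTR;TSS200	Island	0.06	0.98	0.92
cg01270001	7	150020401	LRRC61;ACTR3C;LRRC61;LRRC61;LRRC61	1stExon;5'UTR;5'UTR;5'UTR;1stExon	Island	0.13	0.94	0.81
cg22893248	7	150020751	ACTR3C;ACTR3C;LRRC61;LRRC61	1stExon;5'UTR;5'UTR;5'UTR	Island	0.19	0.73	0.54
cg09327770	12	46663270	SLC38A1;SLC38A1	TSS200;TSS200	Island	0.02	0.83	0.81
cg20463033	12	46663274	SLC38A1;SLC38A1	TSS200;TSS200	Island	0.01	0.77	0.76
cg24795297	12	46663281	SLC38A1;SLC38A1	TSS200;TSS200	Island	0.07	0.77	0.71
cg03859162	13	99404887	SLC15A1;SLC15A1	1stExon;5'UTR	Island	0.12	0.66	0.55
cg03485262	14	92980031	RIN3	TSS200	Island	0.04	0.72	0.68
cg08114373	14	92980204	RIN3;RIN3	5'UTR;1stExon	Island	0.17	0.61	0.44
cg18614734	15	96876248	NR2F2;NR2F2;NR2F2;MIR1469;NR2F2	Body;Body;5'UTR;TSS1500;TSS1500	Island	0.18	0.65	0.47
cg01549404	16	55358636	IRX6;IRX6	5'UTR;1stExon	Island	0.11	0.61	0.50
cg01568244	16	67218584	KIAA0895L;EXOC3L	TSS1500;Body	Island	0.14	0.82	0.69
cg01666600	17	21279561	KCNJ12	TSS200	Island	0.05	0.70	0.65
cg03928539	17	21279613	KCNJ12	TSS200	Island	0.08	0.62	0.54
cg01637175	17	21281507	KCNJ12	5'UTR	Island	0.08	0.78	0.70
cg11804833	17	40575289	PTRF;PTRF	1stExon;5'UTR	Island	0.08	0.62	0.54
cg06093379	17	44896080	WNT3;WNT3	5'UTR;1stExon	Island	0.01	0.83	0.82
cg24441185	18	9708096	RAB31	TSS200	Island	0.06	0.92	0.86
cg17289202	18	56530789	ZNF532	5'UTR	Island	0.13	0.80	0.67
cg22932336	19	4535070	PLIN5	5'UTR	Island	0.10	0.88	0.78
cg04532834	19	4535188	PLIN5;PLIN5	1stExon;5'UTR	Island	0.17	0.64	0.46
cg02505409	19	8429160	ANGPTL4;ANGPTL4;ANGPTL4;ANGPTL4	5'UTR;1stExon;5'UTR;1stExon	Island	0.16	0.79	0.63
cg06837791	19	8429491	ANGPTL4;ANGPTL4	1stExon;1stExon	Island	0.17	0.61	0.44
cg12831261	21	45078437	RRP1B;HSF2BP	TSS1500;5'UTR	Island	0.01	0.93	0.92
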