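# source: study Table 3 - targets found only in cotyledons
miRNA	Tissue	Target	Target Annotation	C.Site	Location	Category	TP100M	P-Value
gma-miR171	C25	Glyma15g01820.1	Protein tyrosine kinase	1359	CDS	1	24.2379	0.0013
gma-miR171	C300	Glyma12g08490.1	Putative methyltransferase	434	CDS	1	12.3961	0.0462
gma-miR394	C100	Glyma06g13230.3	Ferredoxin related protein	1070	CDS	1	104.088	0.027
gma-miR394	C100	Glyma06g13230.2	Ferredoxin related protein	685	CDS	1	104.088	0.027
gma-miR394	C100	Glyma14g25810.1	GTPase-activating protein	1013	CDS	1	57.8265	0.0035
gma-miR394	C100	Glyma06g13230.1	Ferredoxin related protein	952	CDS	1	104.088	0.027
gma-miR398	C100	Glyma03g40280.2	Copper/Zinc superoxide dismutase	156	5' UTR	2	57.8265	0.0379
gma-miR398	C100	Glyma03g40280.3	Copper/Zinc superoxide dismutase	156	5' UTR	2	57.8265	0.0379
gma-miR1509	C300	Glyma18g03980.2	No Functional Annotation	2155	3' UTR	0	7.43768	0.0041
gma-miR1513	C300	Glyma08g27950.1	F-box domain containing protein	190	CDS	0	29.7507	0.0402
gma-miR1514	C25	Glyma07g05360.2	No apical meristem protein	773	CDS	0	16.1586	0.0371
gma-miR1515	C300	Glyma09g02920.1	PAZ domain containing protein	2750	CDS	0	57.0223	0.003
gma-miR1531	C100	Glyma16g33400.1	Serine protease inhibitor family	536	3' UTR	3	46.2612	0.0414
gma-miR1532	C25	Glyma10g28900.1	Universal stress protein family	626	3' UTR	4	4.03965	0.015
gma-miR1535	C25	Glyma08g22920.1	Ribose 5-phosphate isomerase	168	CDS	1	60.5947	0.0242
gma-miR2109	C25	Glyma03g14900.1	LRR containing protein	46	CDS	0	88.8723	0.0165
gma-miR4357	C300	Glyma13g01500.1	Alg9-like mannosyltransferase	779	CDS	1	22.3131	0.0089
gma-miR4357	C300	Glyma01g35530.1	Transferase family protein	522	CDS	1	9.91691	0.0114
gma-miR4369	C25	Glyma19g43800.1	Calcineurin-like phosphoesterase	1257	3' UTR	4	4.03965	0.0468
gma-miR4371	C300	Glyma15g08400.4	No Functional Annotation	452	3' UTR	0	17.3546	0.0017
gma-miR4380	C300	Glyma06g10840.1	MYB family transcription factor	630	CDS	1	9.91691	0.0347
gma-miR4387	C300	Glyma08g43670.1	Uncharacterized conserved protein	1501	CDS	0	4.95846	0.0068
gma-miR4390	C100	Glyma15g06380.1	Dynamin family protein	287	CDS	3	104.088	0.0251
gma-miR4398	C25	Glyma02g25150.1	Integrase domain containing protein	199	5' UTR	4	4.03965	0.0444
gma-miR4402	C300	Glyma02g18090.1	Lectin domain containing protein	783	CDS	4	2.47923	0.0293
gma-miR4403	C300	Glyma19g36500.1	No Functional Annotation	1860	3' UTR	4	2.47923	0.0484
gma-miR4408	C25	Glyma16g34800.1	No functional annotation	434	CDS	1	68.674	0.0057
gma-miR4409	C25	Glyma16g04060.3	BTB/POZ domain containing protein	1304	3' UTR	0	12.1189	0.0144
gma-miR4415	C100	Glyma02g20490.2	Transferase family protein	502	CDS	1	57.8265	0.0463
gma-miR4415	C100	Glyma02g20490.1	Transferase family protein	502	CDS	1	57.8265	0.0463
gma-miR4415	C100	Glyma15g12430.1	Transferase family protein	464	CDS	1	57.8265	0.0463
gma-miR4416	C100	Glyma01g44970.1	BTB/POZ domain containing protein	434	CDS	0	161.914	0.0318
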