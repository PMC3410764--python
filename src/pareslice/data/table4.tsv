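# source: study Table 4 - targets found only in seed coats
miRNA	Tissue	Target	Target Annotation	C.Site	Location	Category	TP100M	P-Value
gma-miR319	SC100	Glyma12g33640.1	TCP family transcription factor	740	CDS	0	106.396	0.0231
gma-miR319	SC100	Glyma15g09910.1	TCP family transcription factor	959	CDS	0	69.5668	0.0121
gma-miR393	SC100	Glyma19g27280.1	LRR containing protein	2207	CDS	2	20.4608	0.032
gma-miR393	SC100	Glyma03g36770.1	LRR containing protein	1750	CDS	3	167.779	0.031
gma-miR393	SC100	Glyma16g05500.1	LRR containing protein	2279	CDS	3	20.4608	0.0132
gma-miR393	SC100	Glyma19g39420.1	LRR containing protein	1751	CDS	3	167.779	0.031
gma-miR1508	SC100	Glyma13g35890.1	EF-hand containing protein	517	3' UTR	1	8.18433	0.0385
gma-miR1518	SC100	Glyma15g12180.1	Ubiquitin-protein ligase	273	CDS	1	16.3687	0.02
gma-miR1523	SC25	Glyma20g02470.1	LRR containg protein	407	CDS	1	5.26902	0.0419
gma-miR1526	SC100	Glyma08g09640.1	No Functional Annotation	424	CDS	0	163.687	0.048
gma-miR1526	SC100	Glyma08g09640.2	No Functional Annotation	424	CDS	0	163.687	0.048
gma-miR2119	SC100	Glyma14g24860.1	Alcohol dehydrogenase	99	CDS	2	2488.04	0.0462
gma-miR4374	SC100	Glyma01g36660.1	Ankyrin repeat containing protein	2124	3' UTR	1	8.18433	0.009
gma-miR4377	SC25	Glyma06g04910.1	Cyclin family protein	910	CDS	4	2.63451	0.0297
gma-miR4399	SC100	Glyma17g34370.1	No functional annotation	637	3' UTR	4	4.09216	0.0491
gma-miR4406	SC25	Glyma03g17300.1	Glyoxal oxidase related protein	1489	CDS	0	73.7663	0.0082
gma-miR4407	SC100	Glyma08g15670.1	Peptide transporter family protein	1078	CDS	1	1076.24	0.0159
gma-miR4407	SC100	Glyma05g04810.1	Peptide transporter family protein	918	CDS	1	1076.24	0.0159
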