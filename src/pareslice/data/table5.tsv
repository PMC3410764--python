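# source: study Table 5 - annotation-group comparison between the two degradome datasets
Annotations Unique to Williams	Annotations Unique to Heinong44	Annotations Found in Both Data Sets
Alcohol/Zinc-binding dehydrogenase	Polyubiquitin protein	AGO protein
Alg9-like mannosyltransferase	Plasmamembrane protein	Auxin Response Factor
Aluminium induced protein	Auxin signaling F-BOX protein	Copper/zinc superoxide dismutase
Anion Exchange protein	NADP+	Growth Regulating Factor
Ankyrin repeat containing protein	MtN19-like protein	HD-ZIP Transcription Factor
Ataxin-2 domain containing protein	Serine-type endopeptidase	MYB family Transcription Factor
bHLH family protein	elongation factor	No Apical Meristem protein (NAC Family)
BRE Expressed protein	NSF attachment protein	SBP domain containing protein
BTB/POZ domain containing protein	Autophagy protein	TCP family transcription factor
Calcineurin-like phosphoesterase	embryo-related protein	Nuclear Factor-YA
Cellulose synthase	AP2 transcription factor	Zinc Finger Family protein
Cyclin family protein	heat shock cognate protein
Dynamin family protein	expressed protein
EF-hand containing protein	60 S ribosomal protein
Elongation Factor S-II	Disulfide isomerase
F-box domain containing protein	FAD linked oxidase family protein
Ferredoxin related protein	Auxin inducible transcription factor
Glyoxal oxidase related protein	ribulose-1,5-bisphosphate carboxylase
GTPase-activating protein
Integrase domain containing protein
lectin domain containing protein
LRR containing protein
mRNA capping enzyme
NADP/FAD oxidoreductase
NB-ARC domain containing protein
No Functional Annotation
PAZ domain containing protein
Peptide transporter family protein
Permease family protein
PPR repeat containing protein
Protein tyrosine kinase
Putative methyltransferase
Ras family protein
Ribose 5-phosphate isomerase
Serine protease inhibitor family
Serine-threonine protein kinase
START Domain containing protein
TIR domain containing protein
Transcription factor TFIID
Transferase family protein
Transmembrane protein 14 C
Transporter family protein
UBA domain containing protein
Ubiquitin-protein ligase
Uncharacterized conserved protein
Universal stress protein family
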