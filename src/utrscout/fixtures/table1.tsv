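gene_id	gene_product	conservation	rfam_prediction	riboswitch_notes	transcript_stress_de	protein_stress_de	gfp_stress_response
ZMO0172	Thiamin biosynthesis protein/phosphomethylpyrimidine synthase	Highly conserved	TPP	TPP riboswitch in E. coli			acetate;xylose
ZMO0979	TonB-dependent receptor	Highly conserved	Cobalamin	AdoCbl	Down in acetate stress; down in xylose stress
ZMO1000	5-methyltetrahydropteroyltriglutamate	Highly conserved	Cobalamin	metE in E. coli/Bacillus	Up in xylose		acetate
ZMO0547	chloride channel core	Conserved with Gluconobacter	crcB	Fluoride riboswitches
ZMO0056	Glucosamine/fructose-6-phosphate aminotransferase			glmS ribozyme
ZMO0376	ATP-dependent protease La
ZMO0546	sulfate transporter			ABC transporter family	Up in 5% ethanol stress; up in xylose stress		acetate
ZMO0660	DnaK molecular chaperone DnaK
ZMO1069	molecular chaperone DnaJ	Highly conserved
ZMO1139	Acetolactate synthase large subunit				Up in xylose
ZMO1142	Thioredoxin reductase				Up in xylose stress; down in ethanol	Up	ethanol
ZMO0709	Phosphoribosylaminoimidazole synthetase	Conserved with Lactobacillus
ZMO1137	Phosphoserine phosphatase SerB	Somewhat conserved		serC regulated by glycine riboswitch
ZMO0187	3-deoxy-7-phosphoheptulonate synthase						xylose
ZMO0369	Glucokinase
ZMO0405	ATP-dependent Clp protease ATP-binding subunit ClpA				Up in xylose stress; down in ethanol stress	Up
ZMO0937	Aromatic amino acid aminotransferase				Down in acetate stress; down in xylose stress
ZMO1179	(uracil-5)-methyltransferase				Up in ethanol stress
ZMO1275	Threonine dehydratase	Conserved with Clostridium
ZMO0689	Oxidoreductase domain-containing protein				Down in xylose stress	Up
ZMO0131	Metallophosphoesterase				Down in acetate stress; down in xylose stress
ZMO0748	Cysteine synthase				Up in acetate stress; up in xylose stress
ZMO1034	Calcium-binding EF-hand-containing protein				Up in acetate stress; up in xylose stress	Up
ZMO1113	FAD-dependent pyridine nucleotide-disulfide oxidoreductase				Up in xylose
ZMO0347	RNA-binding protein Hfq	Conserved with Clostridium			Down in ethanol stress	Up	ethanol
ZMO1198	5-aminolevulinate synthase				Down in xylose stress
ZMO1478	6-phosphogluconolactonase						acetate
ZMO0275	ABC transporter
ZMO1399	fatty acid hydroxylase
ZMO1432	Fusaric acid resistance protein
ZMO0367	glucose-6-phosphate 1-dehydrogenase				Up in ethanol stress	Down
ZMO1412	MucR family transcriptional regulator				Down in ethanol stress	Up
ZMO1048	Phosphate ABC transporter inner membrane subunit PstC
ZMO0140	Protein tyrosine phosphatase
ZMO0366	Sugar transporter
ZMO1612	Toluene tolerance family protein
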