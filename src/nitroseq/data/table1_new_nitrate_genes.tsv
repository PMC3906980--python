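agi	description	log2_ratio
AT5G63160	BT1, BTB and TAZ domain protein 1	5.2
AT1G11655	Unknown protein	4.3
AT5G65030	Unknown protein	4.2
AT1G70260	nodulin MtN21 /EamA-like transporter family protein	4.0
AT2G33550	Homeodomain-like superfamily protein	3.7
AT1G68238	Unknown protein	3.7
AT4G34419	Unknown protein	3.6
AT1G02030	C2H2-like zinc finger protein	3.1
AT4G34800	SAUR-like auxin-responsive protein family	3.0
AT5G03330	Cysteine proteinases superfamily protein	2.9
AT1G60050	Nodulin MtN21 /EamA-like transporter family protein	2.9
AT2G45760	BAL, BAP2, BON association protein 2	2.8
AT1G70800	Calcium-dependent lipid-binding (CaLB domain) family protein	2.8
AT4G29905	Unknown protein	2.7
AT3G22942	AGG2, G-protein gamma subunit 2	2.2
AT1G23149	CPuORF29, conserved peptide upstream open reading frame 29	2.2
AT1G23150	Unknown protein	2.2
AT5G65980	Auxin efflux carrier family protein	2.2
AT3G14260	Protein of Unknown function (DUF567)	2.1
AT3G48180	Unknown protein	2.1
AT3G25717	DVL6, RTFL16, ROTUNDIFOLIA like 16	2.1
AT2G41440	Unknown protein	2.1
AT1G13245	DVL4, RTFL17, ROTUNDIFOLIA like 17	2.0
AT1G68825	DVL5, RTFL15, ROTUNDIFOLIA like 15	2.0
AT5G58320	Kinase interacting (KIP1-like) family protein	2.0
AT3G29034	Unknown protein	1.9
AT1G22882	Galactose-binding protein	1.6
AT4G04745	Unknown protein	1.6
AT4G09180	basic helix-loop-helix (bHLH) DNA-binding superfamily protein	1.3
AT1G45249	ABF2, abscisic acid responsive elements-binding factor 2	1.3
AT5G38200	Class I glutamine amidotransferase-like superfamily protein	1.2
AT2G18193	P-loop containing nucleoside triphosphate hydrolases superfamily protein	1.2
AT5G10200	ARM-repeat/Tetratricopeptide repeat (TPR)-like protein	1.2
AT5G52882	P-loop containing nucleoside triphosphate hydrolases superfamily protein	0.9
AT2G31141	Unknown protein	0.8
AT3G48340	Cysteine proteinases superfamily protein	-1.0
AT2G23790	Protein of Unknown function (DUF607)	-1.2
AT1G52120	Mannose-binding lectin superfamily protein	-1.5
AT4G39795	Protein of Unknown function (DUF581)	-1.9
AT3G06550	O-acetyltransferase family protein	-2.0
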