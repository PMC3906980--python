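mirna	chrom	strand	start	end	mature_sequence	star_detected	prior_report	located_in
miR5640	1	-	1653540	1653560	AUGAGAGAAGGAAUUAGAUUC	YES	ath-miR5640	AT1G05570.1 intron
ath-MIR472-5p	1	-	4182266	4182286	AUGGUCGAAGUAGGCAAAAUC	NO	Novel	ath-MIR472 stem loop
ath-MIR8166	1	-	4525316	4525337	AGAGAGUGUAGAAAGUUUCUCA	NO	Novel	Intergenic region AT1G13240-AT1G13245
miR5654-3p	1	+	11786350	11786371	GAAGAUGCUUUGGGAUUUAUUU	NO	miR5654-3p	AT1G32583.1, 5'UTR
ath-MIR829-5p	1	-	11834153	11834173	ACUUUGAAGCUUUGAUUUGAA	YES	Novel	ath-MIR829 stem loop
miR5014a	1	+	24554009	24554029	UGUUGUACAAAUUUAAGUGUA	YES	ath-miR5014a	AT1G65960.1 intron
ath-MIR840-3p	1	-	771385	771405	UUGUUUAGGUCCCUUAGUUUC	YES	Novel	ath-MIR840 stem loop
ath-MIR398a-3p	2	+	1040948	1040968	AAGGAGUGGCAUGUGAACACA	YES	Novel	ath-MIR398a stem loop
ath-MIR8180	2	+	2063980	2063998	UGCGGUGCGGGAGAAGUGC	NO	Novel	Intergenic region AT2G05580-AT2G05590
ath-MIR8175	2	+	3740938	3740957	GAUCCCCGGCAACGGCGCCA	NO	Novel	Intergenic region AT2G09880-AT2G09890
ath-MIR396a-3p	2	-	4142331	4142351	GUUCAAUAAAGCUGUGGGAAG	YES	Novel	ath-MIR396a stem loop
ath-MIR8168	2	+	5080690	5080710	AGGUGCUGAGUGUGCUAGUGC	NO	Novel	Intergenic region AT2G12490-AT2G12500
ath-MIR5632-5p	2	-	8392588	8392608	UUGAUUCUCUUAUCCAACUGU	YES	Novel	ath-MIR5632 stem loop
ath-MIR8167a	2	+	8894985	8895006	AGAUGUGGAGAUCGUGGGGAUG	NO	Novel	Intergenic region AT2G20620-AT2G20625
miR5995b	2	-	10026977	10026997	AAAGAUGCAGAUCAUAUGUCC	YES	ath-miR5995b	Intergenic region AT2G23540-AT2G23550
ath-MIR831-5p	2	+	10247259	10247280	AGAAGCGUACAAGGAGAUGAGG	NO	Novel	ath-MIR831 stem loop
miR5637	2	-	12270195	12270216	UAGAGGAAAAUAUAGAGUUGGG	NO	ath-miR5637	Intergenic region AT2G28620-AT2G28625
ath-MIR8170.1	2	+	14100020	14100040	AUAGCAAAUCGAUAAGCAAUG	YES	Novel	AT2G33255.1 intron
ath-MIR8170.2	2	+	14100079	14100099	UUGCUUAAAGAUUUUCUAUGU	YES	Novel	AT2G33255.1 intron
ath-MIR160a-3p	2	+	16340342	16340362	GCGUAUGAGGAGCCAUGCAUA	YES	Novel	ath-MIR160a stem loop
ath-MIR8171	2	+	16890466	16890486	AUAGGUGGGCCAGUGGUAGGA	NO	Novel	AT2G40440.1 intron
ath-MIR166a-5p	2	+	19176128	19176148	GGACUGUUGUCUGGCUCGAGG	YES	Novel	ath-MIR166 stem loop
ath-MIR408-5p	2	+	19319866	19319886	ACAGGGAACAAGCAGAGCAUG	YES	Novel	ath-MIR408 stem loop
miR5650	2	+	19686959	19686979	UUGUUUUGGAUCUUAGAUACA	YES	ath-miR5650	AT2G48140.1 intron
miR173-5p	3	+	8236161	8236182	UUCGCUUGCAGAGAGAAAUCAC	YES	ath-miR173-5p	ath-miR173-5p stem loop
ath-MIR8169	3	+	8836359	8836379	AUAGACAGAGUCACUCACAGA	NO	Novel	Intergenic region AT3G24340-AT3G24350
ath-MIR8183	3	-	11747799	11747819	UUUAGUUGACGGAAUUGUGGC	NO	Novel	AT3G30110.1, pseudogene
ath-MIR8165	3	-	16538510	16538530	AAUGGAGGCAAGUGUGAAGGA	NO	Novel	Intergenic region AT3G45170-AT3G45180
ath-MIR8174	3	-	16589431	16589451	AUGUGUAUAGGGAAGCUAAUC	NO	Novel	Intergenic region AT5G38460-AT5G38470
miR5651	3	+	17178489	17178509	UUGUGCGGUUCAAAUAGUAAC	YES	ath-miR5651	Intergenic region AT3G46616-AT3G46620
ath-MIR8167b	3	-	8894985	8895006	AGAUGUGGAGAUCGUGGGGAUG	NO	Novel	Intergenic region AT3G47410-AT3G47420
ath-MIR8167c	3	-	17469946	17469967	AGAUGUGGAGAUCGUGGGGAUG	NO	Novel	Intergenic region AT3G50700-AT3G50710
miR5633	3	+	19544786	19544807	AUGAUCAUCAGAAAACAGUGAU	NO	ath-miR5633	Intergenic region AT3G52730-AT3G52740
ath-MIR393b-3p	3	+	20691778	20691798	AUCAUGCGAUCUCUUUGGAUU	YES	Novel	ath-MIR393 stem loop
ath-MIR8182	3	+	22678166	22678187	UUGUGUUGCGUUUCUGUUGAUU	NO	Novel	AT3G61270.1, 5'UTR
ath-MIR166b-5p	3	+	22922212	22922232	GGACUGUUGUCUGGCUCGAGG	YES	Novel	ath-MIR166 stem loop
ath-MIR8172	4	-	7102572	7102592	AUGGAUCAUCUAGAUGGAGAU	YES	Novel	Intergenic region AT4G11800-AT4G11810
ath-MIR8179	4	-	7161930	7161950	UGACUGCAUUAACUUGAUCGU	NO	Novel	AT4G1192.1 intron
ath-MIR8176	4	+	11795199	11795219	GGCCGGUGGUCGCGAGAGGGA	NO	Novel	Intergenic region AT4G22320-AT4G22330
ath-MIR8178	4	+	18087285	18087305	UAACAGAGUAAUUGUACAGUG	NO	Novel	AT4G38760.1 intron
ath-MIR8184	5	-	3311974	3311994	UUUGGUCUGAUUACGAAUGUA	NO	Novel	Intergenic region AT5G10504-AT5G10510
miR5629	5	+	3802933	3802954	UUAGGGUAGUUAACGGAAGUUA	NO	ath-miR5629	Intergenic region AT5G11790-AT5G11800
ath-MIR865.2	5	+	5169992	5170011	UCUGGGAUGAAUUUGGAUCU	NO	Novel	ath-MIR865 stem loop
miR1888	5	+	7168879	7168899	UAAGUUAAGAUUUGUGAAGAA	NO	ath-miR1888	AT5G21100.1 intron
ath-MIR8173	5	-	7478572	7478592	AUGUGCUGAUUCGAGGUGGGA	NO	Novel	Intergenic region AT5G22510-AT5G22520
ath-MIR8177	5	-	9362634	9362655	GUGUGAUGAUGUGUCAUUUAUA	NO	Novel	Intergenic region AT5G26617-AT5G26620
miR5638b	5	+	14100017	14100037	ACAGUGGUCAUCUGGUGGGCU	NO	ath-miR5638b	Intergenic region AT5G35945-AT5G35950
ath-MIR160c-3p	5	-	19009095	19009115	CGUACAAGGAGUCAAGCAUGA	YES	Novel	ath-MIR160c stem loop
ath-MIR870-5p.1	5	-	21395592	21395612	UUAGAAUGUGAUGCAAAACUU	NO	Novel	ath-MIR870 stem loop
ath-MIR870-5p.2	5	-	21395604	21395624	AAGAACAUCAAAUUAGAAUGU	NO	Novel	ath-MIR870 stem loop
ath-MIR8181	5	-	21641289	21641308	UGGGGGUGGGGGGGUGACAG	NO	Novel	AT5G5333.1, intron
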