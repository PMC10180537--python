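# Published summary catalogue of conserved Cuminum cyminum (cumin) miRNAs:
# highest-read-count members per family, with the matched reference mature
# miRNA and the mismatch count of the homology match. Used as a reference
# input for catalogue-statistics checks.
family	name	sequence	length	reference_mirna	mismatches	read_count
MIR156	cci-miR156d-3p	GCTCTCTATGCTTCTGTCATCA	22	stu-miR156d-3p	0	213619
MIR156	cci-miR156	TTGACAGAAGATAGAGAGCAC	21	bgy-miR156	0	155965
MIR156	cci-miR156a	TGACAGAAGAGAGTGAGCACA	21	bna-miR156a	0	14927
MIR159	cci-miR159a	TTTGGATTGAAGGGAGCTCTA	21	ath-miR159a	0	177734
MIR159	cci-miR319b	TTGGACTGAAGGGAGCTCCCT	21	ath-miR319b	0	5257
MIR159	cci-miR319d-3p	CTTGGACTGAAGGGAGCTCCC	21	ppt-miR319d-3p	0	346
MIR160	cci-miR160h	TGCCTGGCTCCCTGCATGCCA	21	ptc-miR160h	0	149
MIR160	cci-miR160a-3p	GCGTATGAGGAGCCAAGCATA	21	gma-miR160a-3p	0	7
MIR160	cci-miR160d	TGCCTGGCTCCCTGAATGCCA	21	cpa-miR160d	0	1
MIR164	cci-miR164b-5p	TGGAGAAGCAGGGCACGTGCA	21	ath-miR164b-5p	0	1596
MIR164	cci-miR164d	TGGAGAAGCAGGGCACATGCT	21	mtr-miR164d	0	116
MIR164	cci-miR164g-3p	CACGTGCTCCCCTTCTCCA	19	zma-miR164g-3p	0	36
MIR164_2	cci-miR164b	TGGAGAAGCAGGGCACTT	18	far-miR164b	0	3
MIR166	cci-miR166c	TCGGACCAGGCTTCATTCCTC	21	mtr-miR166c	0	140263
MIR166	cci-miR166u	TCTCGGACCAGGCTTCATT	19	gma-miR166u	0	2404
MIR166	cci-miR166c-5p	GGAATGTTGTCTGGCTCGAGG	21	gma-miR166c-5p	0	1176
MIR167	cci-miR167h	TTGAAGCTGCCAGCATGA	18	gma-miR167h	0	9
MIR167_1	cci-miR167d	TGAAGCTGCCAGCATGATCTGG	22	ath-miR167d	0	21213
MIR167_1	cci-miR167c-5p	TGAAGCTGCCAGCATGATCTGC	22	tae-miR167c-5p	0	2262
MIR167_1	cci-miR167d.2	TGAAGCTGCCAGCATGATCTGA	22	cpa-miR167d	0	1244
MIR168	cci-miR168c-5p	TCGCTTGGTGCAGGTCGGGAC	21	bra-miR168c-5p	0	694
MIR168	cci-miR168	TCCCGCCTTGCATCAATTGAAT	22	aau-miR168	1	13
MIR168	cci-miR168a-5p	TCGCTTGGTGCAGATCGGGAC	21	osa-miR168a-5p	0	13
MIR169_1	cci-miR169k	TAGCCAAGGATGACTTGCCTGC	22	bna-miR169k	0	232
MIR169_1	cci-miR169n	TAGCCAAGAATGACTTGCCT	20	osa-miR169n	0	52
MIR169_1	cci-miR169h	TAGCCAAGGATGACTTGCCTG	21	ath-miR169h	0	3
MIR169_2	cci-miR169a-5p	CAGCCAAGGATGACTTGCCGA	21	ath-miR169a-5p	0	91
MIR169_2	cci-miR169r-3p	GGCAAGTTGTCTTTGGCTACA	21	zma-miR169r-3p	1	45
MIR169_2	cci-miR169a-3p	GGCAAGTTGTCTTTGGCTAC	20	ath-miR169a-3p	1	11
MIR171_1	cci-miR171b-3p	TTGAGCCGTGCCAATATCACG	21	ath-miR171b-3p	0	879
MIR171_1	cci-miR171d-5p	TTGGCCGGGCTCACTCAGA	19	osa-miR171d-5p	1	470
MIR171_1	cci-miR171d	TGATTGAGCCGTGCCAATATC	21	cpa-miR171d	0	172
MIR172	cci-miR172c-5p	GTAGCATCATCAAGATTCACA	21	mtr-miR172c-5p	0	217
MIR172	cci-miR172d-5p	AGCACCATCAAGATTCACA	19	zma-miR172d-5p	0	174
MIR172	cci-miR172a	AGAATCTTGATGATGCTGCAT	21	ath-miR172a	0	38
MIR319	cci-miR319i	TTGGGCTGAAGGGAGCTCCC	20	ptc-miR319i	0	7
MIR390	cci-miR390b	AAGCTCAGGAGGGATAGCGCC	21	ppt-miR390b	0	196
MIR390	cci-miR390a-3p	CGCTATCTATCCTGAGTTTCA	21	ath-miR390a-3p	1	63
MIR390	cci-miR390	AAGCACAGGATGGATAGCG	19	pta-miR390	1	14
MIR393	cci-miR393a-5p	TCCAAAGGGATCGCATTGATCC	22	ath-miR393a-5p	0	66
MIR393	cci-miR393	TCCAAAGGGATCGCATTGAT	20	ghr-miR393	0	23
MIR393	cci-miR393c-3p	ATCATGCTATCCCTTTGGATT	21	gma-miR393c-3p	0	19
MIR3932	cci-miR3932a	TCGTCGTCATCACAAAGTT	19	ath-miR3932a	1	1
MIR394	cci-miR394b-5p	TTGGCATTCTGTCCACCTCC	20	ath-miR394b-5p	0	119
MIR395	cci-miR395b	CTGAAGTGTTTGGGGGAACTCC	22	sly-miR395b	0	821
MIR395	cci-miR395o	GAGTTCCTCCAAACACTT	18	osa-miR395o	0	3
MIR395	cci-miR395a	CTGAAGTGTTCGGGGGAACTC	21	ath-miR395a	1	2
MIR396	cci-miR396f	TTCCACGGCTTTCTTGAACTG	21	ptc-miR396f	0	41200
MIR396	cci-miR396	TTCCACAGCTTTCTTGAACTT	21	pta-miR396	0	28712
MIR396	cci-miR396a-3p	GTTCAATAAAGCTGTGGGAAG	21	ath-miR396a-3p	0	6661
MIR397	cci-miR397	ATTGAGTGCAGCGTTGATGA	20	lja-miR397	0	21
MIR398	cci-miR398a-3p	TGTGTTCTCAGGTCACCCCTT	21	ath-miR398a-3p	0	85
MIR398	cci-miR398c	TGTGTTCTCAGGTCGCCCCTG	21	gma-miR398c	0	81
MIR398	cci-miR398a-5p	GGAGTGTCATGGGAACACA	19	aly-miR398a-5p	1	4
MIR399	cci-miR399i	TGCCAAAGGAGAATTGCCCTG	21	gma-miR399i	0	15
MIR399	cci-miR399i.2	TGCCAAAGGAGAGTTGCCCTA	21	ptc-miR399i	0	15
MIR399	cci-miR399d	TGCCAAAGGAGATTTGCCCCG	21	ath-miR399d	0	1
MIR403	cci-miR403-3p	TTAGATTCACGCACAAACTCG	21	ath-miR403-3p	0	4500
MIR403	cci-miR403a	TTAGATTCACGCACAAACTT	20	gma-miR403a	0	471
MIR403	cci-miR403-5p	TTAGATTCACGCACAAAA	18	bra-miR403-5p	0	7
MIR408	cci-miR408	TGCACTGCCTCTTCCCTGG	19	cpa-miR408	0	35
MIR414	cci-miR414	TGACGATGATGATGATGATG	20	ath-miR414	1	1
MIR437	cci-miR437x-5p	GTTTGACTTAGGACAACTCTA	21	sbi-miR437x-5p	0	2
MIR444	cci-miR444b.2	TGCAGTTGTTGTCTCAAGCTT	21	osa-miR444b.2	0	2
MIR444	cci-miR444b	CTTGAGACAGCAACTGCA	18	hvu-miR444b	0	1
MIR444	cci-miR444d.3	TTGTGGCTTTCTTGCAAGTTG	21	osa-miR444d.3	0	1
MIR477	cci-miR477-5p	ACTCTCCCTCAAAGGCTTC	19	ppe-miR477-5p	0	455
MIR477	cci-miR477a	ACTCTCCCTCAAGGGCTTCTG	21	nta-miR477a	0	265
MIR477	cci-miR477a-5p	TCTCCCTCAGAGGCTTCC	18	ptc-miR477a-5p	0	1
MIR482	cci-miR2118	TTTCCTATTCCACCCATCCCAT	22	pgi-miR2118	0	43
MIR529	cci-miR529-5p	AGAAGAGAGAGAGTACAGCCT	21	zma-miR529-5p	0	1
MIR774	cci-miR774b-5p	GTCATCCAAACCTTCATCT	19	aly-miR774b-5p	1	1
MIR818	cci-miR1130b-3p	TTATATTAAGGGACGGAGG	19	tae-miR1130b-3p	1	15
MIR818	cci-miR1436	ACATTATGAGACGGAGGGAGT	21	osa-miR1436	1	2
MIR818	cci-miR1439	TTTTGGGACGGAGTGAGTA	19	osa-miR1439	1	1
MIR821	cci-miR821d	CAACTTTGTTGTTGTTGAC	19	sbi-miR821d	1	1
MIR821	cci-miR821e	AAGTCATCAAAACAAAAGT	19	sbi-miR821e	1	1
MIR827	cci-miR827	TTAGATGATCATCAGCAAACA	21	osa-miR827	1	5537
MIR827	cci-miR827-5p	TTTGTTGGTGGTCATCTAA	19	bdi-miR827-5p	1	251
MIR827	cci-miR827.2	TTAGATGAACATCAGCAAACA	21	nta-miR827	1	3
MIR828	cci-miR828	TCTTGCTTAAATGAGTGTTCCA	22	ath-miR828	1	24
MIR834	cci-miR834	TGGTAGCAGTAGTGGTGGT	19	ath-miR834	1	2
MIR835	cci-miR835-5p	TTCTTGCATATGTTCTTT	18	ath-miR835-5p	0	1
MIR845_3	cci-miR845b	CAATTGGTATCAGAGCTA	18	vvi-miR845b	0	2
MIR858	cci-miR858a	TTTCGTTGTCTGTTCGACCTT	21	ath-miR858a	0	1090
MIR858	cci-miR858b	TTCGCTGTCTGTTCGACCTTG	21	ath-miR858b	1	3
MIR858	cci-miR858-3p	TTCGTTGTCTGCTCGACC	18	aly-miR858-3p	0	2
MIR862	cci-miR862-3p	ATATGCTGGATTTACTTGAAG	21	ath-miR862-3p	1	1
MIR1120	cci-miR1120a	TTATATTATGAGACGGAG	18	tae-miR1120a	0	5
MIR1122	cci-miR1133	GGACGGAGGGAGTATATG	18	tae-miR1133	0	3
MIR1122	cci-miR5281e	ATAAATAGAACCGGAGGGAG	20	mtr-miR5281e	1	2
MIR1511	cci-miR1511	ACCTAGCTCTGATACCATGA	20	mdm-miR1511	0	2
MIR1520	cci-miR1520q	ACCAATTAGAACATGACACA	20	gma-miR1520q	1	1
MIR1863	cci-miR1863b	AGCTCTGATACCATATTAACTG	22	osa-miR1863b	1	4
MIR2084	cci-miR2084	CCTGCATTGGTGGATTGTG	19	ppt-miR2084	1	1
MIR2275	cci-miR2275b-3p	AGATATTAGAGAAAACTGA	19	zma-miR2275b-3p	1	3
MIR2275	cci-miR2275d-5p	AGAGTTGGAGTAAAGAAAA	19	zma-miR2275d-5p	1	1
MIR2646	cci-miR2646b	ATGACATGTAGTGATGATGT	20	mtr-miR2646b	1	1
MIR2673	cci-miR2673b	CCTCTTCCTCTTCCTCTTCC	20	mtr-miR2673b	0	2
MIR2912	cci-miR2912a	TCTAGAACTCCAGATATGG	19	peu-miR2912a	1	3
MIR3630	cci-miR3630-3p	TGGGAATCTCTTTGATGCAC	20	vvi-miR3630-3p	1	3
MIR5067	cci-miR5181-3p	CACTTATTTTGGAACGGAGGG	21	ata-miR5181-3p	1	4
MIR5067	cci-miR5049d	ACAACTATTTAGGAACGGAG	20	hvu-miR5049d	1	3
MIR5067	cci-miR5181-5p	GACAATTATTCTGGATCGG	19	ata-miR5181-5p	1	1
MIR5298	cci-miR5298a	TTCTTCATCTTCATCTCAT	19	mtr-miR5298a	1	1
MIR5387	cci-miR5387b	CTTTAGCACCGGCCAGAGCCAC	22	sbi-miR5387b	1	1
MIR5564	cci-miR5564a	TGGGGAAGCAATTCGTCGAACA	22	sbi-miR5564a	0	23
MIR5564	cci-miR5564b	GCAATTCGTCGAACAGCTTG	20	sbi-miR5564b	0	15
MIR5565	cci-miR5565b	TCGCATCAATCCACATGTGTT	21	sbi-miR5565b	1	1
MIR5568	cci-miR5568d-5p	TGGCTTTTCTAGACACATAGC	21	sbi-miR5568d-5p	1	1
MIR6161	cci-miR6161b	TGGACCAGTATACTTTGCT	19	nta-miR6161b	1	1
MIR6476	cci-miR6476a	TCAGTGGAGATGAAACATG	19	ptc-miR6476a	0	97
MIR7982	cci-miR7982a	TGGAGGATAATAATATATA	19	stu-miR7982a	1	1
MIR7996	cci-miR7996b	TGGTATATATGAAATTTGAA	20	stu-miR7996b	1	1
MIR8762	cci-miR8762c	CAACAAAGTTAGCAAACGT	19	gra-miR8762c	1	2
NA	cci-miR6478	CCGACCTTAGCTCAGTTGGT	20	ptc-miR6478	0	5673
NA	cci-miR6300	GTCGTTGTAGTATAGTGG	18	gma-miR6300	0	4672
NA	cci-miR894	CGTTTCACGTCGGGTTCACC	20	ppt-miR894	0	744
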