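# Published catalogue of novel Cuminum cyminum (cumin) miRNA candidates:
# name, mature sequence (5'-3', RNA), length, read count, genome strand,
# and MFEI of the predicted precursor. Used as a reference input for
# catalogue-statistics checks.
name	sequence	length	read_count	strand	mfei_of_precursor
cci-miRN1-3p	UGCUCACUCUCUAUCUGUCACC	22	8	+	1.41
cci-miRN2-3p	GGCGUACCGUGAGCCAAGCAUGC	23	975	-	0.77
cci-miRN3-5p	UAGAAGUGUGACCUGUCUUGCAU	23	11	-	0.90
cci-miRN4-3p	GCAAGGCAGGACACCUUCUAUG	22	194	-	0.98
cci-miRN5-5p	CAGAAGUGUGACCUGUCUUGCAU	23	83	-	0.98
cci-miRN6-5p	UGACAGAAGAGAGUGAGCACA	21	6	-	0.98
cci-miRN7-5p	UGACAGAAGAGAGUGAGCACA	21	6	-	1.08
cci-miRN8-5p	AUUUUAGCUGAAGUAUUUAGUAU	23	5	+	0.75
cci-miRN9-3p	UAGGCAGGCAUUUUUGGCUAGC	22	6	+	0.94
cci-miRN10-3p	UUUAUGGUGAUUUAUUUGUGUGG	23	1382	-	1.18
cci-miRN11-5p	AAACAAAUUCAUCACCAUAAGGA	23	10	-	1.18
cci-miRN12-3p	UUAUGGUGAUUUAUUUGUGUGGG	23	20	-	1.04
cci-miRN13-3p	GAGUGAAUGAAGCGGGAGACUUAU	24	2	-	0.99
cci-miRN14-5p	UAGCUGCUGACUCAUUCAUCCAA	23	12	-	0.99
cci-miRN15-3p	UCAUCUACGCUGCACUCAAUCAU	23	224	-	0.95
cci-miRN16-5p	GGAAUGUUGUCCGGCUCGAUGCU	23	5	-	1.01
cci-miRN17-3p	CUGAUGCAUGAUGUGAGAGCAA	22	6	-	0.90
cci-miRN18-5p	GCUGUCAUCUCAUGCAUUUGGU	22	24	-	0.90
cci-miRN19-3p	CUGAGCCGAACCAAUAUUACUC	22	177	+	0.92
cci-miRN20-5p	GCGUAAUAUUGCUCCGGCUCAGC	23	262	+	0.92
cci-miRN21-5p	AUUUGGCAUUCUGUUCACCUCCA	23	35	+	1.05
cci-miRN22-3p	UGGUGCCACACUGCUCGCGUUU	22	40	-	1.00
cci-miRN23-3p	GCGCUAUCUAUUCUGAGUUUCA	22	134	+	1.00
cci-miRN24-5p	UAGCUGCCGACUCAUUCACUCA	22	8	+	0.89
cci-miRN25-3p	UUUAGUUUUCUCCAAUUUCUCAU	23	67	-	0.81
cci-miRN26-3p	CUUAGUUUUCUCCGAUAUCUCAU	23	10	-	1.12
cci-miRN27-3p	GCAUGUGCUCUUGCUCUCCUGCU	23	52	+	1.12
cci-miRN28-5p	GCAUGCUCCCUUUUUUAUUGGC	22	6	-	0.85
cci-miRN29-3p	CAAGAUACUCUGAAGAAGCUAGC	23	11	-	0.81
cci-miRN30-5p	AUAUUGGCCGGGCUCACUCAGA	22	6	+	0.93
cci-miRN31-3p	UUAACUAUGCGGUCAAAACUCUU	23	5	-	0.80
cci-miRN32-5p	GUUCCCUUGACCACUUCAUUGG	22	34	-	1.10
cci-miRN33-3p	UCGAACGAUGCAGGGGUUGUGUU	23	110	-	0.92
cci-miRN34-3p	UACAUUGAGGGAAAUUGAGGGA	22	83	+	1.17
cci-miRN35-3p	AUCGGACCAGGCUUCAUUCCUC	22	3	-	0.98
cci-miRN36-5p	GGGAUGUUGGCUGGCUCGAUGC	22	7	-	0.98
cci-miRN37-3p	CAAUGUUUCAUUGCGGGUGUGA	22	8	-	0.98
cci-miRN38-5p	CCUCAAUUUCCCUCAGUGUAGU	22	35	-	1.14
cci-miRN39-5p	UGCUUUGUAUAUUUGGAUUUGAU	23	5	-	0.70
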