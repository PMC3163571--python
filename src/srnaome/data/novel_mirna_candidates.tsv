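name	nt	sequence	n_sequences	genome_hits	miranda_score	precursor_len	mfei
a34_130677_	21	AUAGAUAUUGAUAUGCUUUUA	1	4	163	94	-1.0573
a24_2602_	21	UGCUACAUGGUUUAUCAGUGA	2	5	115	72	-1.2524
a24_177791_	21	UCGCAGAAGAGAUGGCGCCGA	7	1	143	91	-0.8587
a23_118111_	21	CAUUGAUAGACACUAAUAGAA	1	5	167	90	-1.475
a33_14294_	21	AUAGACUUCUAUUGGUGUCUA	1	1	154	74	-1.5105
a32_31625_	21	GUUCCCACGGUAAUGAUAAUA	2	1	127	72	-1.1045
a32_1324_	21	AGGUGUCAUCUUGCUGCGAUA	1	1	179	99	-1.2
a22_190223_	21	UGUUAUGCAUGGCGUCGGGAG	1	5	187	157	-1.2915
a14_98657_	21	AUAGCGAAGUAUAUCAGUGAU	1	1	154	127	-1.2423
a14_51701_	21	UGAGCCGUGCCAAUAUCGACG	1	1	159	97	-1.1
a14_180374_	21	UAAAUAUUUAGAAAGUCAAUC	1	4	159	79	-1.855
a21_80766_	21	UAAUAUUCAUUUUCACUUCUU	1	1	116	232	-1.2494
a21_78863_	21	UGCAUCCUGAGGUUUAGGGAG	3	1	159	194	-0.9776
a21_244426_	21	AGUAACCACUAAGCUAAUGGC	1	1	187	597	-1.0096
a23_1441_	21	UAUAGCAAAGUCUAUCGAUGG	5	1	107	77	-1.1435
a13_84447_	21	GGUCAUUCUAGCAGCUUCAAU	13	1	139	201	-0.96
a23_370_	21	UGGUGUGCAUGUGAUGGAAUA	13	1	163	113	-0.9061
a21_134553_	21	GUUAUACGAGUUGGGUUGGGU	1	1	155	114	-0.9571
a11_95657_	21	UUGUGUCAUUGACAUUGUGGU	1	2	195	191	-1.1708
a14_9427_	21	UCGUCCUGAGAAUACAUGUCA	35	1	159	97	-0.9409
a14_668_	21	UGAGUUAUCGGUGAAUUCAAG	5	3	159	516	-0.9675
a13_252112_	21	ACUGCUGCUUGUACUAUUGAA	1	1	191	255	-1.9670
a11_33177_	21	UUUAGUUUAGCCUAUUGCUUU	1	3	187	139	-1.1035
a11_191362_	21	UUCUAUUGUCUUCAUUUGUGA	1	1	191	119	-1.2718
a34_224062_	21	UGAAAUGACUUGUCAAGUGCU	1	1	151	97	-0.975
a13_228150_	21	CUUGUACUUGAUUUUGUUGCC	1	1	191	115	-1.4469
a12_32299_	21	AAUUUGUUGGUCAAAUGAUUG	2	1	195	107	-1.7552
a12_272161_	21	UUGUAUGGUGGAAAGAUGGAA	1	1	162	96	-1.4167
a11_33986_	21	GCUGACUUGCUGAUUGAGUUA	2	3	179	189	-1.4852
a13_33760_	21	UGAAUUAUCUGCUUAAGUUUU	1	1	187	95	-1.2889
a11_389198_	21	ACACGCAGAAGAGACGAUUGA	1	1	191	120	-1.5575
a13_357842_	21	UGGAGCAAUAUUGAUGCAUAU	1	1	195	220	-0.9548
a11_364692_	21	UUGGGUCUAUUUAAUGGGAGC	1	1	155	107	-1.2308
a13_281334_	21	ACUUUCUGUCAAUAUAAUCAG	1	1	175	115	-1.3943
a12_71107_	21	UAUCAUAGUUGGUGGUUCAGG	3	1	143	115	-1.2167
a13_120551_	21	UCAACGAUAGACAUUGAUAGA	1	1	171	107	-1.2875
a12_123886_	21	UUAUCAUUGAUAGACUAGUAU	1	2	155	174	-1.0612
a11_227522_	21	CAAGCCCAUGACAAAGCAAGC	1	1	187	225	-1.0929
a14_133932_	21	UCAACACGAUCGUCUAGCAUG	1	2	173	113	-1.2295
a11_203340_	21	UUUGAGUGUCCUACUCACCUC	1	1	191	411	-1.0833
a11_11135_	21	UAGUGCCGCGCUGCGUGCGUC	85	1	147	102	-0.98
a11_31022_	21	UUUCGCUUUUCCUCUUUCGUG	1	1	191	454	-1.1523
a12_144938_	21	UCGUGGAUAUUGCUCUUUUCU	2	1	171	504	-1.3303
a33_181157_	22	GAUAGAUACUAAUAUGCUUCUA	1	2	188	87	-1.3227
a33_37151_	22	AGAUUAAUUUAUUGGGCGUUAU	1	2	144	94	-1.3313
a12_72169_	22	UUGAGCUAUGCUCAGGUUGACA	30	1	176	174	-1.2933
a24_96796_	22	UGAGCUAUGCUCGCUUUGGCAA	21	1	175	169	-1.2855
a11_378153_	22	GAGUUCCUAAGUUUUGAUGAAU	1	1	144	351	-1.2221
a11_378297_	22	UUUUGGAUUCUAUCGAUGAAAG	1	1	155	123	-1.4857
a23_244052_	22	GGGCAGCCCCACGUUGGGCAUG	5	1	175	353	-0.9263
a11_85662_	22	AAAUAUAUCGGUGUCUAUCAAU	1	2	132	85	-1.2208
a21_388555_	22	GAUAGACGCUGAUAGAUAGACA	3	1	124	76	-0.8963
a11_84237_	22	CGGCCAAAAAUGACUUGCCCGG	2	1	150	105	-0.8902
a23_124460_	22	AGGUGAGUUCUUUUUAUAGGCU	1	1	184	179	-1.6306
a23_163065_	22	AUUUGAUUAGCCAAAUUUAAAC	2	2	148	130	-1.0514
a23_71826_	22	CAAUAGUCAGAUGUAAACGAUC	1	1	180	228	-1.4282
a22_52587_	22	AAAAUUAUUGGGUGAAUUAGUU	2	1	179	162	-0.9013
a13_234225_	22	UGAAUUUUGUUAUGUUUUGUAA	1	2	168	80	-2.0417
a13_286453_	22	AGUCUAUCACCGAUAGAAGCCU	1	6	182	430	-1.4372
a21_339397_	22	CGCGAGGUUCUUUGUUUGUCUU	1	1	192	413	-1.3341
a14_283014_	22	UACCUAGUGAUGCCAUUGUCAA	1	1	184	533	-1.2829
a21_170878_	22	CUAAGGUUGCCCAGAGAUGUUC	1	1	163	271	-1.2341
a21_63125_	22	GAAUAAUUAUCAAGUGUGUAGC	1	1	165	210	-1.7804
a11_146182_	24	UUAAAAUGUUGCUAUAUAAUUAAU	1	6	202	390	-1.6207
a21_169735_	24	UAUACGGGCCGUAAAUAGUUUGAU	2	6	132	369	-0.8885
a23_3672_	24	UUGCUCAUUGCUAACUGCAAAGAG	1	3	198	183	-1.7594
a14_260703_	24	UUAAAAGUAUGAGACGAAAAUGAA	1	1	190	111	-1.4204
a14_218837_	24	UUAAAAAGAACUACACGAACGUGC	1	1	194	342	-1.1314
a14_148530_	24	AAAUAGCGUCGGGGAAAGGUGUCU	3	1	152	73	-1.0167
a21_127379_	24	UGGGACAAAAGAAAACUGUGGGUC	2	1	162	586	-1.32
a11_2899_	24	AUGAUGCUUUGGUGCUAAGGAGGU	1	1	198	470	-1.6094
a11_248538_	24	AUUUUUGGCAUUUUACACGGUGAG	2	2	192	218	-1.5206
a13_59670_	24	AGUGGAGUGGGCUAUUUUAGUCCA	6	1	166	570	-1.1249
a32_72333_	24	AACUAUUUUAUUGGAACAUGUUGA	3	1	170	96	-1.0391
a33_22103_	24	AGUAUGAUCUCGGGCUAAGGUUGC	1	4	202	246	-1.4138
a24_224684_	24	AACAAAACGAAUGAUCAAAAUGGU	3	1	134	80	-0.8871
a13_225824_	24	ACCAAAUGGAUCUAUUCUUAUAAU	1	1	198	311	-1.3393
a24_82972_	24	AACGAUCGGGUUGACUACGUAAAU	3	1	190	146	-0.9354
a21_98074_	24	AAUUUUUAGUGGUCCCGAAAUGCA	3	1	166	112	-0.9033
a11_350684_	24	UGAGUGUAUCAUCGAGAUAGUGCG	1	1	190	307	-1.1642
a21_216237_	24	AAAUUUCAGGGUCUAAAUUGAUGC	2	1	138	447	-1.2096
a33_49599_	24	CAGCGUGAUUGAUGGGGCAUUUUU	3	1	118	287	-1.4678
a33_58155_	24	AUGGUCGAUCUCAACCGAGAUUGA	1	1	194	298	-1.3188
a23_103110_	24	CGUGAAGAUUGUGGAUAUUGGAGA	1	1	190	414	-1.5507
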