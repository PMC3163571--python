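annotation	sequence	similarity_pct	mirna_reads	star_reads	genome_hit
miR156|a, b, c, d, e, f	UGACAGAAGAGAGUGAGCAC	100	469	60	YES
miR157|a, b, c	UUGACAGAAGAUAGAGAGCAC	100	269	0	YES
miR157|d	UGACAGAAGAUAGAGAGCAC	100	19	21	YES
miR158|a	UCCCAAAUGUAGACAAAGCA	100	1	0	--
miR159|a	UUUGGAUUGAAGGGAGCUCUA	100	14651	0	YES
miR159|b	UUUGGAUUGAAGGGAGCUCUU	100	18	0	--
miR159|c	UUUGGAUUGAAGGGAGCUCCU	100	1	0	--
miR160|a, b, c	UGCCUGGCUCCCUGUAUGCCA	100	537	0	YES
miR161|a.1	UUGAAAGUGACUACAUCGGGG	100	6	0	--
miR161|a.2	UCAAUGCAUUGAAAGUGACUA	100	1	0	--
miR162|a, b	UCGAUAAACCUCUGCAUCCAG	100	825	0	YES
miR164|a, b	UGGAGAAGCAGGGCACGUGCA	100	172	1	YES
miR165|a, b	UCGGACCAGGCUUCAUCCCCC	100	4	0	--
miR166|a, b, c, d, e, f, g	UCGGACCAGGCUUCAUUCCCC	100	65	27	YES
miR167|a, b	UGAAGCUGCCAGCAUGAUCUA	100	136	0	YES
miR167|d	UGAAGCUGCCAGCAUGAUCUGG	100	16	1	--
miR168|a, b	UCGCUUGGUGCAGGUCGGGAA	100	967	0	YES
miR169|a	CAGCCAAGGAUGACUUGCCGA	100	3	1	--
miR169|b, c	CAGCCAAGGAUGACUUGCCGG	100	76	1	YES
miR169|h, i, j, k, l, m, n	UAGCCAAGGAUGACUUGCCUG	100	83	1	YES
miR170|a	UGAUUGAGCCGUGUCAAUAUC	100	3	0	--
miR171|a	UGAUUGAGCCGCGCCAAUAUC	100	85	5	YES
miR171|b, c	UUGAGCCGUGCCAAUAUCACG	100	64	0	YES
miR172|a	AGAAUCUUGAUGAUGCUGCAU	100	85	58	YES
miR172|c, d	AGAAUCUUGAUGAUGCUGCAG	100	4	0	YES
miR172|e	GGAAUCUUGAUGAUGCUGCAU	100	3	0	YES
miR319|a, b	UUGGACUGAAGGGAGCUCCC	100	2	3	YES
miR390|a, b	AAGCUCAGGAGGGAUAGCGCC	100	32	6	YES
miR391|a	UUCGCAGGAGAGAUAGCGCCA	100	1	0	--
miR393|a, b	UCCAAAGGGAUCGCAUUGAUC	100	18	0	YES
miR394|a, b	UUGGCAUUCUGUCCACCUCC	100	4	0	YES
miR396|a	UUCCACAGCUUUCUUGAACUG	100	134	84	YES
miR396|b	UUCCACAGCUUUCUUGAACUU	100	82	16	YES
miR397|a	UCAUUGAGUGCAGCGUUGAUG	100	26	0	YES
miR408|a	AUGCACUGCCUCUUCCCUGGC	100	14	1	YES
ath-miR2111a	UAAUCUGCAUCCUGAGGUUUA	100	1	0	YES
peu-miR2910	UAGUUGGUGGAGCGAUUUGUC	100	8	0	YES
osa-miR167d	UGAAGCUGCCAGCAUGAUCUG	100	3401	1	YES
tae-miR395b	UGAAGUGUUUGGGGGAACUC	100	1	0	YES
bna-miR397a	CAUUGAGUGCAGCGUUGAUGU	95	77	0	YES
miR156|h	UUGACAGAAGAGAGUGAGCAC	95	91	0	YES
miR156|g	ACAGAAGAGAGUGAGCACA	90	5	0	YES
miR169|d, e, f, g	UGAGCCAAGGAUGACUUGCCU	95	130	0	YES
miR169|d, e, f, g	UGAGCCAAAGAUGACUUGCCU	90	112	0	YES
miR399|a	UGCCAAAAGAGACUUGCCCUG	95	3	0	YES
miR403|a	CUAGAUUCACGCACAAGCUCG	90	1	0	--
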