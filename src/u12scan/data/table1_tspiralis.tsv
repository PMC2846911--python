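est_id	terminal_group	exon5	intron_5p	intron_3p	exon3	intron_length	burge	rule	relationship	ce_gene	gene_function
EX501652.1	ATAC	AGA	ATATCCTTTC	TTGGGCATTGTTATATTTCCTTAACGGGTATGGTTTAC	GTT	2095	+	+	U12->U2	EEED8.7	SR (splicing factor)
EX500683.1	ATAC	ATT	ATATCCTTTC	AATTTCATTTCCTTAACGTTAGATTTTTGTTGTTTTAC	TGA	94	+	+	U12 lost	E04D5.1a	NA
ES570647.1	ATAC	ATC	ATATCCTTTC	GTATTGTTTGTATTTTCCTTAACTTCATATGTTTTTAC	GTA	182	+	+	U12 lost	Y37D8A.10	Signal peptidase complex, subunit SPC25
EX499999.1	GTAG	GAG	GTATCCTTTG	TTTTGTTTTTCTCTCTTTTTACAATTATTATACAG	GCC	90	-	+	U12->U2	F10F2.1	PH, BEACH and WD40 domain-containing protein
ES570692.1	GTAG	TAG	GTATTGTTTT	TGCTACAAGGAATTTTTTTATTGCTTTGATTTTAG	AGT	617	-	-	U12->U2	F40F8.10	Small ribosomal subunit S9 protein
ES561213.1	GTAG	TCG	GTATTATTTT	CATATTAATCGTTTCATTTCTTAATGTATTTTTAG	TGG	54	-	-	U12->U2	ZC395.10	NA
EX500486.1	GTAG	TCG	GTATTCTTTC	TAATATGTTTTTCTTTTTTTTCAACTTATTTTAAG	ATT	87	-	+	U12->U2	ZC328.3a	NA
ES569928.1	GTAG	ATG	GTATTCTTTT	ATTTCCATTACAAAATTACAACCGCGTTGTTCTTTCAG	TGC	107	+	+	Not known	Y82E9BR.15	Transcription elongation factor B
ES565768.1	GTAG	CAG	GTATTCTTTT	CAAATTTTGGAAAAATTCTTTTTTTTTAATCCGAACAG	GTA	94	-	+	Not known	C34D4.4a	NA
ES562099.1	GTAG	AAT	GTATCCTTAA	TGTATGAGGTTTGGTATTTCTGATTTTAATCATTTTAG	TGT	50	-	+	Not known	R07E5.14	RRM RNA binding domain containing
ES563059.1	GTAG	GCG	GTATCTTTTC	TATTTATAACTGAATCGTTTTTATTAATAATTTTTTAG	AGT	54	-	+	Not known	M04F3.4	NA
BQ738460.1	GTAG	ACG	GTATCGTTCA	TCAATTTTTTTAAAAGTAATTTTCTTCATATATTTTAG	AAC	72	-	-	U12 lost/Not known	Y56A3A.36	NA
ES566079.1	GTAG	TGG	GTATCGTTCG	ATTAACTAACACTTTGAAGTTGACAAGTGAATGTTTAG	GAT	140	-	-	Not known	M02B7.4	beta-1,4-N-acetylglucosaminyl transferase
EX500543.1	GTAG	TCG	GTATTCTTTG	TTATTATTAATTTCTGTTTTTTTTGGTTTTCTAAACAG	AGA	86	-	+	NA	None	NA
ES561535.1	GTAG	GGG	GTATTATTTT	TTTTCTGTGATTTAATTGCATTTTAATGTTCTATCTAG	TGA	71	-	-	NA	None	NA
BQ738918.1	GTAG	GAA	GTATCTTTTA	TGAATTTTGCTAAATTGTACTTAACAGGTTGTTTTTAG	AAA	153	-	+	NA	None	NA
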