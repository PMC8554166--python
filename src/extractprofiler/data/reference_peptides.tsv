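# Reference set of verified and predicted emulsifier and antioxidant peptides
# from enzymatic Eucheuma denticulatum protein extracts, transcribed from the
# published literature. Columns: annotation; peptide_class (alpha/beta/gamma
# emulsifier conformation, SCA free-radical scavenger, CHE metal chelator);
# status (verified in vitro vs predicted only); predictor score; parent
# protein ID(s) in the de-novo transcriptome database (semicolon-separated);
# sequence; published length; published net charge at pH 7; published
# length-normalized relative abundance (%) of the parent protein in the
# Viscozyme (V), Alcalase (A) and Shearzyme+Celluclast (SC) extracts by
# semi-specific analysis.
annotation	peptide_class	status	score	parents	sequence	length	charge_ph7	ilrel_v	ilrel_a	ilrel_sc
80-S-A	alpha	verified	3.3	c7052_g1_i1;c7052_g1_i2	IGYTVRNSLRVTVRDLSNLGLILDALVR	28	2	12.9	24.5	9.6
81-S-A	alpha	verified	2.9	c7052_g1_i1	AVKDAVRRATLLTKAAGTGLGKVLS	25	4	8.6	14.6	6.9
83-S-B	beta	verified	3.18	c7052_g1_i1;c7052_g1_i2	RAGSNSLSRISFGISNEADLRDQAR	25	1	12.9	24.5	9.6
84-S-B	beta	verified	2.75	c6313_g1_i1	VGFACSGSAQTYLSFEGDNTGRGEEEVAI	29	-4.1	1.3	5.7	1.1
85-S-B	beta	verified	3.27	c7052_g1_i1	LSIREGGRSTGGFSAQVRAR	20	3	8.6	14.6	6.9
86-S-B	beta	verified	5.43	c7052_g1_i1	ELQVSARVTLEIEL	14	-2	8.6	14.6	6.9
87-S-G	gamma	verified	5.72	c1505_g2_i1	RELQRDDNVRNVRILLSSLVLLLDWLVCLL	30	-0.1	27.4	30.8	26.4
88-S-G	gamma	verified	5.06	c1505_g2_i1	AVLVVCLQQVRELQRDDNVRN	21	-0.1	27.4	30.8	26.4
pEa-1	alpha	predicted	3.77	c1545_g1_i1	VKRISGLIYEETRNVLKVF	19	2	2.8	0.0	7.4
pEa-2	alpha	predicted	3.64	c13559_g1_i1;c6825_g1_i1	IYKVLKQV	8	2	2.2	0.0	8.1
pEa-3	alpha	predicted	3.62	c10861_g1_i1	RFFLRVVRGVRQKV	14	5	0.5	3.7	0.6
pEa-4	alpha	predicted	3.44	c14987_g1_i1	VQKLSRVID	9	1	0.0	0.0	0.0
pEa-5	alpha	predicted	3.37	c6825_g1_i1	VADLFERIASEAAKL	15	-1	2.2	0.0	8.1
pEb-1	beta	predicted	4.80	c7216_g1_i1	VRIRVDCK	8	1.9	2.5	5.4	2.8
pEb-2	beta	predicted	4.12	c14987_g1_i1	RLNCKID	7	0.9	0.0	0.0	0.0
pEb-3	beta	predicted	3.72	c4419_g1_i1	LKVELNSGGQMR	12	1	1.7	0.0	2.0
pEb-4	beta	predicted	3.55	c907_g1_i1	NIQKESTLHLVLRLRGGL	18	2.1	15.1	5.3	6.6
pEb-5	beta	predicted	3.20	c13533_g1_i1	AKVRVTC	7	1.9	2.2	0.0	4.3
pEg-1	gamma	predicted	5.20	c13533_g1_i1	ITTVLALVCVITQVMQASANEQEHVHEHEH	30	-3.7	2.2	0.0	4.3
pEg-2	gamma	predicted	5.11	c24_g1_i1.p2	ILLVLCLSWLRRKVCRNHR	19	5	0.0	3.4	0.2
pEg-3	gamma	predicted	5.10	c10861_g1_i1	EREYELQKEFATLVLAVV	18	-2	0.5	3.7	0.6
pEg-4	gamma	predicted	4.69	c17933_g1_i1	FLLVFFFFFTDEDT	14	-3	5.2	13.5	6.2
pEg-5	gamma	predicted	4.43	c907_g1_i1	QDQQRLIFA	9	0	15.1	5.3	6.6
120-S-SCA	SCA	verified	0.49	c6313_g1_i1	RYVWN	5	1	1.3	5.7	1.1
123-S-SCA	SCA	verified	0.38	c6313_g1_i1	DFPVR	5	0	1.3	5.7	1.1
124-S-SCA	SCA	verified	0.43	c17304_g1_i1	AGDWLIGDR	9	-1	9.8	3.9	2.3
pSCA-1	SCA	predicted	0.72	c6963_g1_i1	DFYAYIVFTWAGYHGVDLAKNKIASDF	27	-0.9	2.7	0.9	5.2
pSCA-2	SCA	predicted	0.71	c24_g1_i1	WYHY	4	0.1	0.0	3.4	0.2
pSCA-3	SCA	predicted	0.66	c10861_g1_i1	LQGSKFAVVEYGGIVDPILGLQP	23	-1	0.5	3.7	0.6
pSCA-4	SCA	predicted	0.64	c13533_g1_i1	ASANEQEHVHEHEHIIRTFS	20	-2.6	2.2	0.0	4.3
pSCA-5	SCA	predicted	0.64	c4419_g1_i1	VVPFSSWYAEQQRI	14	0	1.7	0.0	2.0
pCHE-1	CHE	predicted	0.39	c17933_g1_i1	FFFFTDEDTFPSGPSLTTFCSP	22	-3.1	5.2	13.5	6.2
pCHE-2	CHE	predicted	0.36	c6405_g1_i2	FAISLFRIFPASFMFMPFTH	20	1.1	0.0	0.0	0.0
pCHE-3	CHE	predicted	0.35	c6405_g1_i2	PHPN	4	0.1	0.0	0.0	0.0
pCHE-4	CHE	predicted	0.34	c7216_g1_i1	FFSALLLLMNFPSPTMSLCTDDD	23	-3.1	2.5	5.4	2.8
pCHE-5	CHE	predicted	0.34	c13559_g1_i1;c24_g1_i1;c6405_g1_i2;c6656_g1_i1;c6825_g1_i1	HP	2	0.1	4.2	0.1	9.9
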