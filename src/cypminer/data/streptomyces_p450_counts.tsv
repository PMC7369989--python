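species	n_p450	n_families	n_subfamilies
Streptomyces sp. Tu6071	22	13	20
Streptomyces sp. CNT372	10	8	10
Streptomyces purpureus KA281, ATCC 21405	22	17	20
Streptomyces sp. CNS606	16	9	14
Streptomyces sp. W007	28	12	24
Streptomyces sp. 303MFCol5.2	23	14	22
Streptomyces sp. TAA486-18	18	12	17
Streptomyces acidiscabies 84-104	47	22	44
Streptomyces lysosuperificus ATCC 31396	25	19	24
Streptomyces roseosporus NRRL 11379	19	10	16
Streptomyces sp. PVA 94-07	20	7	18
Streptomyces sp. OspMP-M45	19	9	19
Streptomyces sp. SPB78	20	12	20
Streptomyces sp. AmelKG-A3	19	9	19
Streptomyces canus 299MFChir4.1	28	17	27
Streptomyces sp. S4	19	9	19
Streptomyces sp. FxanaA7	30	15	29
Streptomyces sp. SM8	18	8	16
Streptomyces sulphureus DSM 40104	26	13	25
Streptomyces sp. LaPpAH-199	26	11	21
Streptomyces sp. MspMP-M5	44	20	41
Streptomyces sp. 140Col2.1E	22	9	17
Streptomyces coelicoflavus ZG0656	17	12	16
Streptomyces sp. DvalAA-21	24	10	22
Streptomyces pristinaespiralis ATCC 25486	18	11	17
Streptomyces sp. CNT371	17	13	17
Streptomyces sp. LaPpAH-201	19	8	19
Streptomyces somaliensis DSM 40738	10	8	9
Streptomyces albulus CCRC 11814	64	26	50
Streptomyces sp. 351MFTsu5.1	22	11	22
Streptomyces viridochromogenes DSM 40736	24	15	24
Streptomyces sp. DvalAA-83	24	10	22
Streptomyces sp. LaPpAH-95	24	9	22
Streptomyces sp. AmelKG-F2B	24	17	23
Streptomyces mirabilis YR139	42	26	41
Streptomyces sp. CNT302	26	13	22
Streptomyces sp. AA1529	26	15	24
Streptomyces olindensis DAUFPE 5622	26	14	22
Streptomyces atratus OK008	15	10	14
Streptomyces sp. CNY243	17	14	16
Streptomyces sp. PsTaAH-130	36	21	32
Streptomyces sp. AA0539	19	10	19
Streptomyces sp. CNT318	27	15	24
Streptomyces atratus OK807	31	13	27
Streptomyces sp. CNH099	16	12	16
Streptomyces sp. CNS335	16	13	17
Streptomyces sp. CNH287	16	12	16
Streptomyces sp. FxanaC1	27	15	24
Streptomyces sp. MnatMP-M77	32	14	27
Streptomyces sp. WMMB 322	19	11	17
Streptomyces zinciresistens K42	19	11	18
Streptomyces sp. TOR3209	20	13	19
Streptomyces sp. So1WspMP-so12th	22	11	19
Streptomyces sp. AmelKG-E11A	24	15	22
Streptomyces sp. GXT6	13	8	11
Streptomyces sp. PP-C42	16	6	14
Streptomyces roseosporus NRRL 15998	19	10	16
Streptomyces sp. DpondAA-E10	25	10	22
Streptomyces sp. LaPpAH-108	24	12	23
Streptomyces sp. HPH0547	32	18	32
Streptomyces aurantiacus JA 4570	30	20	30
Streptomyces sp. DpondAA-A50	25	10	22
Streptomyces hygroscopicus ATCC 53653	57	21	49
Streptomyces sp. TAA040	15	10	15
Streptomyces sp. Tu 6176	30	15	26
Streptomyces sp. PgraA7	23	10	20
Streptomyces ghanaensis ATCC 14672	35	20	34
Streptomyces sp. FxanaD5	15	11	15
Streptomyces sp. KhCrAH-337	26	12	22
Streptomyces sp. LamerLS-316	25	11	22
Streptomyces sp. LaPpAH-202	19	8	19
Streptomyces viridochromogenes Tue57	31	17	29
Streptomyces sp. UNC401CLCol	15	11	15
Streptomyces sp. GBA 94-10	20	7	18
Streptomyces sp. SirexAA-H	21	12	20
Streptomyces sp. CNQ-525	18	14	18
Streptomyces turgidiscabies Car8	28	20	27
Streptomyces sp. SceaMP-e96	41	18	36
Streptomyces sp. KhCrAH-40	26	12	22
Streptomyces mirabilis OK461	37	16	31
Streptomyces rimosus rimosus ATCC 10970	54	30	52
Streptomyces sp. LaPpAH-185	44	27	40
Streptomyces gancidicus BKS 13-15	18	11	17
Streptomyces exfoliatus DSMZ 41693	26	16	24
Streptomyces auratus AGR0001	35	14	33
Streptomyces sp. PsTaAH-137	29	16	28
Kitasatospora sp. SolWspMP-SS2h	25	15	24
Streptomyces sp. Amel2xE9	27	15	26
Streptomyces sp. NTK 937	17	8	17
Streptomyces sp. AmelKG-D3	22	11	19
Streptomyces sp. ScaeMP-e48	19	10	17
Streptomyces prunicolor NBRC 13075	44	18	39
Streptomyces sp. HmicA12	25	14	24
Streptomyces sp. e14	28	13	25
Streptomyces griseoaurantiacus M045	16	11	16
Streptomyces sp. CNX435	12	9	12
Streptomyces afghaniensis 772	28	17	29
Streptomyces sp. HCCB10043	17	10	14
Streptomyces sulphureus L180	19	11	19
Streptomyces sp. JS01	24	11	19
Streptomyces sp. KhCrAH-340	26	12	22
Streptomyces chartreusis NRRL 3882	29	19	26
Streptomyces sp. C	30	17	27
Streptomyces sp. CNY228	19	9	19
Streptomyces violaceusniger SPC6	13	8	12
Streptomyces sp. Amel2xB2	27	13	25
Streptomyces sp. HGB0020	23	13	22
Streptomyces sp. LaPpAH-165	24	9	22
Streptomyces sp. CNS615	27	15	24
Streptomyces albulus ZPM	68	27	51
Streptomyces tsukubaensis NRRL 18488	30	18	30
Streptomyces albulus NK660	64	27	50
Streptomyces vitaminophilus DSM 41686	18	10	15
Streptomyces noursei	64	26	52
Streptomyces sp. SA3_actG	21	12	20
Streptomyces violaceusniger Tu4113	50	16	42
Streptomyces bottropensis ATCC 25435 (2517572239)	31	19	30
Streptomyces bingchenggensis	49	26	44
Streptomyces sp. CNQ865	16	13	16
Streptomyces rapamycinicus	63	23	56
Streptomyces sp. CNT360	19	13	18
Streptomyces sp. 769	59	24	49
Streptomyces sp. 142MFCol3.1	27	14	24
Streptomyces hygroscopicus subsp. jinggangensis 5008	38	18	33
Streptomyces sp. ScaeMP-e122	25	11	23
Streptomyces cattleya NRRL 8058 = DSM 46488	41	21	38
Streptomyces griseoflavus Tu4000	20	15	19
Streptomyces cattleya NRRL 8057	40	20	37
Streptomyces sp. ACT-1	30	13	26
Streptomyces hygroscopicus subsp. jinggangensis TL01	37	18	33
Streptomyces sp. TAA204	18	10	16
Streptomyces avermitilis MA-4680	52	23	42
Streptomyces sp. SPB74	18	10	18
Streptomyces collinus	34	16	27
Streptomyces sp. CNQ329	13	10	13
Streptomyces lydicus A02	38	19	35
Streptomyces sp. 4F	16	11	15
Streptomyces lydicus 103	32	13	29
Streptomyces sp. KhCrAH-244	26	12	22
Streptomyces sp. Mg1	37	21	36
Streptomyces chartreusis NRRL 12338	23	15	23
Streptomyces leeuwenhoekii C34(2013)	36	17	34
Streptomyces sviceus ATCC 29083	19	12	19
Streptomyces pratensis/flavogriseus IAF 45	29	16	26
Streptomyces sp. CcalMP-8W	23	12	20
Streptomyces reticuli	47	26	43
Streptomyces sp. SS	15	11	15
Streptomyces griseus	28	13	24
Streptomyces sp. CNQ766	16	13	16
Streptomyces sp. PAMC 26508	29	16	26
Streptomyces sp. URHA0041	16	9	15
Streptomyces sp. SirexAA-E	24	10	22
Streptomyces sp. CNB091	27	14	24
Streptomyces davawensis	32	19	30
Streptomyces flavidovirens DSM 40150	24	15	23
Streptomyces cyaneogriseus	30	14	28
Streptomyces yeochonensis CN732	18	11	18
Streptomyces lincolnensis	24	15	23
Streptomyces viridosporus T7A, ATCC 39115	32	19	31
Streptomyces pristinaespiralis HCCB 10218	23	12	18
Streptomyces sp. FXJ7.023	27	12	23
Streptomyces venezuelae	23	16	21
Streptomyces mirabilis OV308	28	14	27
Streptomyces sp. CFMR 7	24	13	20
Streptomyces sp. AW19M42	27	12	24
Streptomyces vietnamensis	30	20	29
Streptomyces sp. ATexAB-D23	28	11	26
Streptomyces xiamenensis 318	19	12	19
Streptomyces sp. BoleA5	17	8	15
Streptomyces coelicolor	18	10	17
Streptomyces sp. AA4	35	17	29
Streptomyces albus J1074	18	9	18
Streptomyces sp. CNS654	27	10	22
Streptomyces ambofaciens	19	10	18
Streptomyces ipomoeae 91-03	44	26	43
Streptomyces lividans	20	10	18
Streptomyces sp. DpondAA-B6	19	9	19
Streptomyces scabiei 87.22	30	16	30
Streptomyces sp. PCS3-D2	25	18	24
Streptomyces glaucescens	18	11	17
Streptomyces sp. PRh5	57	20	51
Streptomyces albus DSM 41398	25	13	24
Streptomyces sp. CNR698	29	17	26
Streptomyces fulvissimus	19	10	16
Amycolatopsis sp. 75iv2, ATCC 39116	28	18	27
Streptomyces sp. CNQ-509	16	11	16
Streptomyces cattleya ATCC 35852	41	21	38
Streptomyces rubrolavendulae	20	12	19
Streptomyces sp. WMMB 714	21	10	18
Streptomyces clavuligerus	64	30	58
Streptomyces scabrisporus DSM 41855	37	27	36
Streptomyces griseochromogenes	46	24	40
Streptomyces sp. Ncost-T6T-1	25	14	22
Streptomyces sp. S10(2016)	20	15	20
Streptomyces sp. CNB632	16	12	16
Streptomyces globisporus	23	13	19
Streptomyces mobaraensis NBRC 13819	22	13	21
Streptomyces sp. CdTB01	26	17	25
Streptomyces sp. KhCrAH-43	26	12	22
Streptomyces parvulus	25	15	25
Streptomyces sp. PsTaAH-124	32	16	27
Streptomyces sp. SAT1	25	15	22
Streptomyces sp. Amel2xC10	15	10	15
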