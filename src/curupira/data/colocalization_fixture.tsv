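contig	mirna_start	mirna_end	mirna_strand	mirna_id	cluster_start	cluster_end	transcription_strand	cluster_id	expression
NODE_413592	23358	23437	+	novel_27198	5015	11188	Mono:-	161	MB-,MB+
NODE_659880	5542	5604	+	novel_4023	71	5034	Mono:-	297	FB+,FB-
NODE_530411	42958	43045	+	novel_33801	46001	52942	Mono:+	230	FB+,FB-
NODE_540432	60460	60520	-	miR-17b-1	58002	63335	Mono:+	235	FB-,FB+,MB-,MB+
NODE_540432	61062	61118	+	novel-34307	58002	63335	Mono:+	235	FB-,FB+,MB-,MB+
NODE_540432	61235	61302	+	novel-34310	58002	63335	Mono:+	235	FB-,FB+,MB-,MB+
NODE_540432	61365	61424	+	novel-34311	58002	63335	Mono:+	235	FB-,FB+,MB-,MB+
NODE_540432	61471	61530	+	novel-34313	58002	63335	Mono:+	235	FB-,FB+,MB-,MB+
NODE_374673	36480	36543	+	miR-146b	35407	36661	Mono:+	146	FB-,FB+,MB-
NODE_347176	36121	36181	+	miR-21-1	35371	38453	Mono:-	134	FB-,FB+
NODE_34239	37421	37486	+	miR-30a-1	36149	39395	Mono:+	133	FB-,MB+
NODE_34239	37756	37816	+	miR-30b	36149	39395	Mono:+	133	FB-,MB+
NODE_158712	303	365	+	miR-10c	304	3733	Mono:+	33	FB+
NODE_56612	1109	1162	+	novel_35680	2	5452		248	FB+
NODE_749189	27328	27349	+	miR-19a-5p	25083	30798	Mono:+	330	FB-,FB+,MB-,MB+
NODE_749189	27674	27696	+	miR-19b-5p	25083	30798	Mono:+	330	FB-,FB+,MB-,MB+
NODE_319315	10039	10120	+	novel_2199	67	10614	Mono:+	127	MB-,MB+
NODE_61639	9	153	+	novel_675	10	4241	Bi:+/-	270	FB+,FB-
NODE_27951	2471	2536	+	novel_262	86	3836	Mono:+	107	FB+,FB-
NODE_960524	12443	12504	+	mir-21a	12344	14456	Mono:-	368	FB+,FB-
NODE_581740	1963	2049	-	novel_3634	91	4010	Mono:-	253	FB+,FB-
NODE_81238	848	916	-	novel_66	169	2856	Mono:-	344	FB-
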