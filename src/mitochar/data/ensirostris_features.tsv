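# Reference annotation of the Exhippolysmata ensirostris mitogenome (GenBank MK681888).
# genome_length=16350 circular=true
Gene	Direction	Start	End	Length	Anticodon	Start codon	Stop codon
nad4	-	13	1239	1227	-	ATG	TAA
nad4l	-	1323	1577	255	-	ATG	TAA
trnT	+	1618	1680	63	ACA	-	-
trnP	-	1686	1748	63	CCA	-	-
nad6	+	1773	2270	498	-	ATA	TAA
cob	+	2272	3408	1137	-	ATG	TAA
trnS2	+	3407	3476	70	TCA	-	-
nad1	-	3564	4433	870	-	ATA	TAG
trnL1	-	4455	4521	67	CTA	-	-
rrnL	-	4499	5866	1368	-	-	-
trnV	-	5858	5921	64	GTA	-	-
rrnS	-	5920	6737	818	-	-	-
CR	+	6738	7986	1249	-	-	-
trnI	+	7987	8053	67	ATC	-	-
trnQ	-	8060	8127	68	CAA	-	-
trnM	+	8129	8195	67	ATG	-	-
nad2	+	8223	9204	982	-	ATG	TAA
trnW	+	9219	9284	66	TGA	-	-
trnC	-	9288	9352	65	TGC	-	-
trnY	-	9354	9418	65	TAC	-	-
cox1	+	9420	10931	1512	-	ATA	TAA
cox2	+	11013	11699	687	-	ATG	TAA
trnL2	+	11756	11821	66	TTA	-	-
trnK	+	11981	12048	68	AAA	-	-
trnD	+	12050	12112	63	GAC	-	-
atp8	+	12113	12277	165	-	ATG	TAA
atp6	+	12271	12936	666	-	ATG	TAA
cox3	+	12951	13733	783	-	ATA	TAA
trnG	+	13740	13806	67	GGA	-	-
nad3	+	13807	14172	366	-	ATG	TAA
trnA	+	14159	14221	63	GCA	-	-
trnR	+	14222	14285	64	CGA	-	-
trnN	+	14285	14349	65	AAC	-	-
trnS1	+	14350	14417	68	AGA	-	-
trnE	+	14418	14486	69	GAA	-	-
trnF	-	14487	14550	64	TTC	-	-
nad5	-	14558	16261	1704	-	ATG	TAA
trnH	-	16280	16343	64	CAC	-	-
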