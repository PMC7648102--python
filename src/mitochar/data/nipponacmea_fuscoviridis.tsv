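# organism=Nipponacmea fuscoviridis	genome_length=18720	circular=true
# Published annotation of the Nipponacmea fuscoviridis mitogenome (GenBank MK395167).
# Length and Intergenic are the values printed in the source annotation table;
# the toolkit recomputes both from the coordinates.  Known printed
# inconsistencies: trnC Length prints 66 where the coordinates span 60 bp, and
# the nad5 Intergenic cell prints 1562 where the coordinates (and the source's
# own prose, which gives the control region as 1561 bp) imply 1561.
Gene	Strand	Start	Stop	Length	StartCodon	StopCodon	Intergenic	Anticodon
cox1	+	1	1551	1551	ATG	TAG	19
trnL2	+	1571	1636	66			2	TAA
cox3	+	1639	2425	787	ATG	T(AA)	99
trnM1	+	2525	2588	64			15	CAT
nad4	-	2604	3905	1302	ATG	TAA	81
trnC	-	3987	4046	66			17	GCA
nad1	+	4064	4999	936	ATG	TAG	5
trnH	+	5005	5072	68			14	GTG
trnA	+	5087	5153	67			84	TGC
nad5	-	5238	6851	1614	ATT	TAG	1562
atp8	+	8413	8574	162	ATG	TAG	3
cox2	+	8578	9265	688	ATG	T(AA)	115
atp6	+	9381	10181	801	ATG	TAG	41
cytb	+	10223	11357	1135	ATG	T(AA)	68
trnG	+	11426	11491	66			6	TCC
trnK	+	11498	11565	68			3	TTT
trnI	+	11569	11640	72			4	GAT
trnP	+	11645	11711	67			2	TGG
trnN	+	11714	11780	67			7	GTT
trnM2	+	11788	11855	68			60	CAT
nad4l	-	11916	12212	297	ATA	TAA	220
trnE	+	12433	12499	67			58	TTC
nad6	+	12558	13046	489	ATA	TAG	4
trnW1	-	13051	13116	66			11	CCA
trnS1	+	13128	13193	66			378	TCT
trnL1	-	13572	13637	66			2	TAG
trnY	-	13640	13706	67			380	GTA
nad3	+	14087	14440	354	GTG	TAG	-11
rrnL	+	14430	15867	1438			16
trnD	+	15884	15948	65			6	GTC
trnR	+	15955	16020	66			11	TCG
trnF	+	16032	16097	66			0	GAA
trnT	-	16098	16166	69			10	TGT
trnW2	-	16177	16243	67			11	TCA
trnQ	+	16255	16321	67			-4	TTG
nad2	-	16318	17355	1038	ATT	TAA	6
trnV	-	17362	17426	65			129	TAC
rrnS	+	17556	18491	936			3
trnS2	+	18495	18561	67			159	TGA
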