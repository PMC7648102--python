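# organism=Lottia goshimai	genome_length=18192	circular=true
# Published annotation of the Lottia goshimai mitogenome (GenBank MT248298).
# Length and Intergenic are the values printed in the source annotation table;
# the toolkit recomputes both from the coordinates.  Known printed
# inconsistency: trnG Length prints 67 where the coordinates span 60 bp.
Gene	Strand	Start	Stop	Length	StartCodon	StopCodon	Intergenic	Anticodon
cox1	+	1	1560	1560	GTG	TAG	26
trnM1	+	1587	1652	66			-20	CAT
nad1	-	1633	2562	930	ATG	TAG	37
trnT	+	2600	2668	69			3	TGT
trnY	-	2672	2738	67			9	GTA
nad5	-	2748	4421	1674	ATT	TAA	178
nad4l	+	4600	4902	303	ATG	TAG	51
nad4	+	4954	6279	1326	ATG	TAG	67
cox3	-	6347	7204	858	ATG	TAA	10
trnG	+	7215	7274	67			11	TCC
trnS2	+	7286	7350	65			8	TGA
trnQ	+	7359	7425	67			22	TTG
atp6	-	7448	8209	762	ATG	TAA	85
cox2	-	8295	8960	666	ATG	TAA	86
trnL1	+	9047	9112	66			5	TAG
trnI	+	9118	9189	72			8	GAT
trnP	+	9198	9265	68			1	TGG
trnF	+	9267	9334	68			43	GAA
nad6	+	9378	9896	519	ATG	TAA	4
nad3	+	9901	10254	354	ATG	TAA	11
trnM2	-	10266	10332	67			45	CAT
trnL2	+	10378	10443	66			12	TAA
trnA	-	10456	10525	70			0	TGC
trnN	-	10526	10593	68			15	GTT
trnW	-	10609	10678	70			14	TCA
nad2	-	10693	11655	963	ATT	TAA	103
trnV	-	11759	11827	69			7	TAC
trnK	+	11835	11903	69			15	TTT
trnS1	+	11919	11985	67			10	TCT
trnD	-	11996	12061	66			76	GTC
rrnS	+	12138	13058	921			11
trnE	+	13070	13139	70			11	TTC
trnC	+	13151	13219	69			-6	GCA
rrnL	+	13214	14746	1533			63
cytb	+	14810	15973	1164	ATG	TAA	28
trnR	+	16002	16070	69			1722	TCG
atp8	-	17793	17951	159	ATG	TAA	145
trnH	+	18097	18166	70			26	GTG
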