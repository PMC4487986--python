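human_gene	species	homologue	similarity	model	provenance
DGCR6	fly	gdl	37	KO	rbh
DGCR6	zebrafish	dgcr6	65	-	rbh
DGCR6	mouse	Dgcr6	92	-	rbh
PRODH	worm	CELE_B0513.5	46	KD	rbh
PRODH	fly	slgA	46	KO,KD	rbh
PRODH	zebrafish	prodha	63	KO	rbh
PRODH	zebrafish	LOC100537991	69	-	rbh
PRODH	mouse	Prodh	82	KO	rbh
DGCR2	zebrafish	dgcr2	64	KO	rbh
DGCR2	mouse	Dgcr2	93	KO	rbh
DGCR14	worm	ess-2	30	KO,KD	rbh
DGCR14	fly	Es2	35	KD	rbh
DGCR14	zebrafish	dgcr14	67	-	rbh
DGCR14	mouse	Dgcr14	93	KO	rbh
TSSK2	mouse	Tssk2	92	KO	rbh
GSC2	zebrafish	LOC101885810	52	-	rbh
GSC2	mouse	Gsc2	76	KO	rbh
SLC25A1	worm	K11H3.3	65	KD	rbh
SLC25A1	fly	sea	67	KO,KD	rbh
SLC25A1	zebrafish	slc25a1a	78	KD	rbh
SLC25A1	zebrafish	slc25a1b	84	-	rbh
SLC25A1	mouse	Slc25a1	94	KO	rbh
HIRA	worm	K10D2.1	33	KO,KD	rbh
HIRA	fly	Hira	60	KO,KD	rbh
HIRA	zebrafish	hira	78	KD	rbh
HIRA	mouse	Hira	96	KO	rbh
MRPL40	worm	mrpl-40	30	KD	rbh
MRPL40	fly	mRpL40	40	KO,KD	rbh
MRPL40	zebrafish	mrpl40	50	-	rbh
MRPL40	mouse	Mrpl40	75	KO	rbh
C22orf39	fly	CG15908	32	KO,KD	rbh
C22orf39	zebrafish	si:ch211-251h9.6	49	-	rbh
C22orf39	mouse	2510002D24Rik	72	KO	rbh
UFD1L	worm	ufd-1	41	KD	rbh
UFD1L	fly	Ufd1-like	56	KO,KD	rbh
UFD1L	zebrafish	ufd1l	87	KO	rbh
UFD1L	mouse	Ufd1l	99	KO	rbh
CDC45	worm	evl-18	29	KO,KD	rbh
CDC45	fly	CDC45L	39	KO,KD	rbh
CDC45	zebrafish	cdc45	74	KO	rbh
CDC45	mouse	Cdc45	92	KO	rbh
CLDN5	zebrafish	cldn5a	57	KO,KD	rbh
CLDN5	zebrafish	cldn5b	54	-	rbh
CLDN5	mouse	Cldn5	92	KO	rbh
SEPT5	zebrafish	sept5a	84	-	rbh
SEPT5	zebrafish	sept5b	85	-	rbh
SEPT5	mouse	Sept5	99	KO	rbh
GP1BB	zebrafish	gp1bb	46	-	rbh
GP1BB	mouse	Gp1bb	90	KO	rbh
TBX1	worm	mls-1	53	KO,KD	rbh
TBX1	fly	org-1	58	KO,KD	rbh
TBX1	zebrafish	tbx1	72	KO,KD	rbh
TBX1	mouse	Tbx1	91	KO	rbh
GNB1L	fly	CG13192	30	KO,KD	rbh
GNB1L	zebrafish	gnb1l	53	-	rbh
GNB1L	mouse	Gnb1l	82	KO	rbh
TXNRD2	worm	trxr-2	49	KO,KD	rbh
TXNRD2	fly	Trxr-2	55	KD	rbh
TXNRD2	zebrafish	si:ch1073-179p4.3	71	-	rbh
TXNRD2	mouse	Txnrd2	86	KO	rbh
COMT	zebrafish	comta	53	-	rbh
COMT	zebrafish	comtb	54	-	rbh
COMT	mouse	Comt	80	KO	rbh
ARVCF	zebrafish	arvcfb	64	KO	rbh
ARVCF	mouse	Arvcf	92	KO	rbh
TANGO2	worm	R186.1	29	KD	rbh
TANGO2	fly	Tango2	30	KO,KD	rbh
TANGO2	zebrafish	tango2	64	-	rbh
TANGO2	mouse	Tango2	88	-	rbh
DGCR8	worm	pash-1	25	KO,KD	rbh
DGCR8	fly	pasha	37	KO,KD	rbh
DGCR8	zebrafish	dgcr8	72	KO	rbh
DGCR8	mouse	Dgcr8	95	KO	rbh
TRMT2A	worm	H24K24.4	27	KD	rbh
TRMT2A	fly	CG3808	37	KO,KD	rbh
TRMT2A	zebrafish	trmt2a	56	KO	rbh
TRMT2A	mouse	Trmt2a	83	KO	rbh
RANBP1	zebrafish	ranbp1	73	KO	rbh
RANBP1	mouse	Ranbp1	93	KO	rbh
ZDHHC8	zebrafish	zdhhc8b	57	KO	rbh
ZDHHC8	mouse	Zdhhc8	92	KO	rbh
LOC388849	mouse	Gm7873	72	-	rbh
RTN4R	zebrafish	rtn4r	45	KD	rbh
RTN4R	mouse	Rtn4r	89	KO	rbh
SCARF2	zebrafish	scarf2	52	-	rbh
SCARF2	mouse	Scarf2	82	KO	rbh
KLHL22	fly	CG1812	30	KO,KD	rbh
KLHL22	zebrafish	klhl22	60	-	rbh
KLHL22	mouse	Klhl22	95	-	rbh
MED15	worm	mdt-15	26	KO,KD	override
MED15	fly	MED15	32	KO,KD	rbh
MED15	zebrafish	med15	60	KD	rbh
MED15	mouse	Med15	90	-	rbh
PI4KA	worm	CELE_Y75B8A.24	38	KO,KD	rbh
PI4KA	fly	PI4KIIIalpha	45	KO,KD	rbh
PI4KA	zebrafish	pi4kaa	84	KD	rbh
PI4KA	mouse	Pi4ka	98	KO	rbh
SERPIND1	zebrafish	serpind1	54	-	rbh
SERPIND1	mouse	Serpind1	82	KO	rbh
SNAP29	worm	snap-29	28	KO,KD	rbh
SNAP29	fly	Snap29	32	KO,KD	rbh
SNAP29	zebrafish	snap29	51	KD	rbh
SNAP29	mouse	Snap29	83	KO	rbh
CRKL	zebrafish	crkl	82	KD	rbh
CRKL	mouse	Crkl	97	KO	rbh
AIFM3	worm	F20D6.11	34	KD	rbh
AIFM3	fly	CG4199	38	KO,KD	rbh
AIFM3	zebrafish	LOC100150876	66	-	rbh
AIFM3	mouse	Aifm3	96	-	rbh
LZTR1	fly	CG3711	51	KO,KD	rbh
LZTR1	zebrafish	lztr1	81	-	rbh
LZTR1	mouse	Lztr1	95	KO	rbh
THAP7	zebrafish	thap7	42	KO	rbh
THAP7	mouse	Thap7	93	-	rbh
P2RX6	mouse	P2rx6	86	KO	rbh
SLC7A4	worm	C50D2.2	43	KD	rbh
SLC7A4	fly	CG13248	43	KO,KD	rbh
SLC7A4	zebrafish	slc7a4	64	KO	rbh
SLC7A4	mouse	Slc7a4	84	-	rbh
LRRC74B	zebrafish	si:ch211-173a9.8	41	-	rbh
LRRC74B	mouse	Lrrc74b	68	-	rbh
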