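species	gene_id	chrom	start	end
mouse	Dgcr6	chr16	1000000	1005000
mouse	Prodh	chr16	1050000	1055000
mouse	Dgcr2	chr16	1100000	1105000
mouse	Dgcr14	chr16	1150000	1155000
mouse	Tssk2	chr16	1200000	1205000
mouse	Gsc2	chr16	1250000	1255000
mouse	Slc25a1	chr16	1300000	1305000
mouse	Hira	chr16	1350000	1355000
mouse	Mrpl40	chr16	1400000	1405000
mouse	2510002D24Rik	chr16	1450000	1455000
mouse	Ufd1l	chr16	1500000	1505000
mouse	Cdc45	chr16	1550000	1555000
mouse	Cldn5	chr16	1600000	1605000
mouse	Sept5	chr16	1650000	1655000
mouse	Gp1bb	chr16	1700000	1705000
mouse	Tbx1	chr16	1750000	1755000
mouse	Gnb1l	chr16	1800000	1805000
mouse	Txnrd2	chr16	1850000	1855000
mouse	Comt	chr16	1900000	1905000
mouse	Arvcf	chr16	1950000	1955000
mouse	Tango2	chr16	2000000	2005000
mouse	Dgcr8	chr16	2050000	2055000
mouse	Trmt2a	chr16	2100000	2105000
mouse	Ranbp1	chr16	2150000	2155000
mouse	Zdhhc8	chr16	2200000	2205000
mouse	Gm7873	chr16	2250000	2255000
mouse	Rtn4r	chr16	2300000	2305000
mouse	Scarf2	chr16	2350000	2355000
mouse	Klhl22	chr16	2400000	2405000
mouse	Med15	chr16	2450000	2455000
mouse	Pi4ka	chr16	2500000	2505000
mouse	Serpind1	chr16	2550000	2555000
mouse	Snap29	chr16	2600000	2605000
mouse	Crkl	chr16	2650000	2655000
mouse	Aifm3	chr16	2700000	2705000
mouse	Lztr1	chr16	2750000	2755000
mouse	Thap7	chr16	2800000	2805000
mouse	P2rx6	chr16	2850000	2855000
mouse	Slc7a4	chr16	2900000	2905000
mouse	Lrrc74b	chr16	2950000	2955000
zebrafish	dgcr8	chr10	1000000	1005000
zebrafish	trmt2a	chr10	1050000	1055000
zebrafish	ranbp1	chr10	1100000	1105000
zebrafish	zdhhc8b	chr10	1150000	1155000
zebrafish	LOC100537991	chr13	1000000	1005000
zebrafish	cldn5a	chr13	1050000	1055000
zebrafish	sept5a	chr13	1100000	1105000
zebrafish	gp1bb	chr13	1150000	1155000
zebrafish	cldn5b	chr17	1000000	1005000
zebrafish	scarf2	chr17	1050000	1055000
zebrafish	klhl22	chr17	1100000	1105000
zebrafish	med15	chr17	1150000	1155000
zebrafish	pi4kaa	chr17	1200000	1205000
zebrafish	serpind1	chr17	1250000	1255000
zebrafish	sept5b	chr21	1000000	1005000
zebrafish	snap29	chr21	1050000	1055000
zebrafish	crkl	chr21	1100000	1105000
zebrafish	LOC100150876	chr21	1150000	1155000
zebrafish	lztr1	chr21	1200000	1205000
zebrafish	thap7	chr21	1250000	1255000
zebrafish	rtn4r	chr25	1000000	1005000
zebrafish	slc7a4	chr25	1050000	1055000
zebrafish	si:ch211-173a9.8	chr25	1100000	1105000
zebrafish	dgcr6	chr4	1000000	1005000
zebrafish	prodha	chr4	1050000	1055000
zebrafish	slc25a1b	chr4	1100000	1105000
zebrafish	comtb	chr4	1150000	1155000
zebrafish	tbx1	chr5	1000000	1005000
zebrafish	gnb1l	chr5	1050000	1055000
zebrafish	si:ch1073-179p4.3	chr5	1100000	1105000
zebrafish	comta	chr5	1150000	1155000
zebrafish	arvcfb	chr5	1200000	1205000
zebrafish	tango2	chr5	1250000	1255000
zebrafish	dgcr2	chr8	1000000	1005000
zebrafish	dgcr14	chr8	1050000	1055000
zebrafish	LOC101885810	chr8	1100000	1105000
zebrafish	slc25a1a	chr8	1150000	1155000
zebrafish	hira	chr8	1200000	1205000
zebrafish	mrpl40	chr8	1250000	1255000
zebrafish	si:ch211-251h9.6	chr8	1300000	1305000
zebrafish	ufd1l	chr8	1350000	1355000
zebrafish	cdc45	chr8	1400000	1405000
fly	pasha	2L	1000000	1005000
fly	CG3808	2L	1050000	1055000
fly	CG1812	2L	1100000	1105000
fly	MED15	2L	1150000	1155000
fly	slgA	2R	1000000	1005000
fly	Es2	2R	1050000	1055000
fly	sea	2R	1100000	1105000
fly	Hira	2R	1150000	1155000
fly	mRpL40	2R	1200000	1205000
fly	CG15908	3L	1000000	1005000
fly	Ufd1-like	3L	1050000	1055000
fly	CDC45L	3L	1100000	1105000
fly	org-1	3L	1150000	1155000
fly	CG13192	3L	1200000	1205000
fly	PI4KIIIalpha	3R	1000000	1005000
fly	Snap29	3R	1050000	1055000
fly	CG4199	3R	1100000	1105000
fly	CG3711	3R	1150000	1155000
fly	CG13248	3R	1200000	1205000
fly	gdl	X	1000000	1005000
fly	Trxr-2	X	1050000	1055000
fly	Tango2	X	1100000	1105000
worm	CELE_B0513.5	I	1000000	1005000
worm	ess-2	I	1050000	1055000
worm	K11H3.3	I	1100000	1105000
worm	K10D2.1	I	1150000	1155000
worm	mrpl-40	II	1000000	1005000
worm	ufd-1	II	1050000	1055000
worm	evl-18	II	1100000	1105000
worm	mls-1	III	1000000	1005000
worm	trxr-2	III	1050000	1055000
worm	R186.1	III	1100000	1105000
worm	pash-1	IV	1000000	1005000
worm	H24K24.4	IV	1050000	1055000
worm	mdt-15	IV	1100000	1105000
worm	CELE_Y75B8A.24	V	1000000	1005000
worm	snap-29	V	1050000	1055000
worm	F20D6.11	V	1100000	1105000
worm	C50D2.2	V	1150000	1155000
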