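gene_id	symbol	chrom	start	end	strand	biotype	brain_signal	brain_expressed	decreased_in_deletion
DGCR6	DGCR6	chr22	18830000	18838000	+	protein_coding	6.5	True	True
PRODH	PRODH	chr22	18855000	18863000	-	protein_coding	7.2	True	True
DGCR5	DGCR5	chr22	18880000	18888000	+	ncRNA			
DGCR9	DGCR9	chr22	18905000	18913000	-	ncRNA			
DGCR10	DGCR10	chr22	18930000	18938000	+	ncRNA			
DGCR2	DGCR2	chr22	18955000	18963000	-	protein_coding	10.0	True	True
GGT3P	GGT3P	chr22	18980000	18988000	+	pseudogene			
DGCR11	DGCR11	chr22	19005000	19013000	-	ncRNA			
DGCR14	DGCR14	chr22	19030000	19038000	+	protein_coding	8.1	True	True
TSSK2	TSSK2	chr22	19055000	19063000	-	protein_coding		False	
GSC2	GSC2	chr22	19080000	19088000	+	protein_coding		False	
SLC25A1	SLC25A1	chr22	19105000	19113000	-	protein_coding	10.2	True	True
POM121L1P	POM121L1P	chr22	19130000	19138000	+	pseudogene			
CLTCL1	CLTCL1	chr22	19155000	19163000	-	protein_coding		True	
DGCR12	DGCR12	chr22	19180000	19188000	+	ncRNA			
HIRA	HIRA	chr22	19205000	19213000	-	protein_coding	9.0	True	True
MRPL40	MRPL40	chr22	19230000	19238000	+	protein_coding	9.7	True	True
BCRP2	BCRP2	chr22	19255000	19263000	-	pseudogene			
C22orf39	C22orf39	chr22	19280000	19288000	+	protein_coding		True	True
MIR185	MIR185	chr22	19305000	19313000	-	miRNA		True	
UFD1L	UFD1L	chr22	19330000	19338000	+	protein_coding	8.5	True	True
CDC45	CDC45	chr22	19355000	19363000	-	protein_coding	9.2	True	True
CLDN5	CLDN5	chr22	19380000	19388000	+	protein_coding	9.9	True	True
POM121L7P	POM121L7P	chr22	19405000	19413000	-	pseudogene			
SEPT5	SEPT5	chr22	19430000	19438000	+	protein_coding	7.3	True	True
SEPT5-GP1BB	SEPT5-GP1BB	chr22	19455000	19463000	-	read_through			
GP1BB	GP1BB	chr22	19480000	19488000	+	protein_coding	3.1	False	True
BCRP5	BCRP5	chr22	19505000	19513000	-	pseudogene			
TBX1	TBX1	chr22	19530000	19538000	+	protein_coding	10.1	True	False
GNB1L	GNB1L	chr22	19555000	19563000	-	protein_coding	6.8	True	True
C22orf29	C22orf29	chr22	19580000	19588000	+	protein_coding		True	
TXNRD2	TXNRD2	chr22	19605000	19613000	-	protein_coding	8.2	True	True
COMT	COMT	chr22	19630000	19638000	+	protein_coding	8.9	True	True
ARVCF	ARVCF	chr22	19655000	19663000	-	protein_coding	9.6	True	True
GGTLC4P	GGTLC4P	chr22	19680000	19688000	+	pseudogene			
TANGO2	TANGO2	chr22	19705000	19713000	-	protein_coding	7.0	True	True
MIR3618	MIR3618	chr22	19730000	19738000	+	miRNA		False	
DGCR8	DGCR8	chr22	19755000	19763000	-	protein_coding	8.4	True	True
MIR1306	MIR1306	chr22	19780000	19788000	+	miRNA		True	
TRMT2A	TRMT2A	chr22	19805000	19813000	-	protein_coding	9.8	True	True
RANBP1	RANBP1	chr22	19830000	19838000	+	protein_coding	6.5	True	True
KRT18P62	KRT18P62	chr22	19855000	19863000	-	pseudogene			
ZDHHC8	ZDHHC8	chr22	19880000	19888000	+	protein_coding	7.9	True	True
RPL23AP82	RPL23AP82	chr22	19905000	19913000	-	pseudogene			
LOC388849	LOC388849	chr22	19930000	19938000	+	protein_coding		True	
HMGB1P22	HMGB1P22	chr22	19955000	19963000	-	pseudogene			
RTN4R	RTN4R	chr22	19980000	19988000	+	protein_coding	6.7	True	False
MIR649	MIR649	chr22	20005000	20013000	-	miRNA		False	
MTND5P22	MTND5P22	chr22	20030000	20038000	+	pseudogene			
EEF1A1P22	EEF1A1P22	chr22	20055000	20063000	-	pseudogene			
HNRNPA1P73	HNRNPA1P73	chr22	20080000	20088000	+	pseudogene			
DGCR6L	DGCR6L	chr22	20105000	20113000	-	protein_coding		True	
SNRPGP14	SNRPGP14	chr22	20130000	20138000	+	pseudogene			
YWHAEP7	YWHAEP7	chr22	20155000	20163000	-	pseudogene			
DUXAP11	DUXAP11	chr22	20180000	20188000	+	pseudogene			
USP41	USP41	chr22	20330000	20338000	-	protein_coding		True	
ZNF74	ZNF74	chr22	20363000	20371000	+	protein_coding	9.7	True	
PI4KAP1	PI4KAP1	chr22	20396000	20404000	-	pseudogene			
SCARF2	SCARF2	chr22	20429000	20437000	+	protein_coding	7.1	True	True
KLHL22	KLHL22	chr22	20462000	20470000	-	protein_coding	7.8	True	True
MED15	MED15	chr22	20495000	20503000	+	protein_coding	8.5	True	True
FAM230A	FAM230A	chr22	20528000	20536000	-	ncRNA			
PI4KAP2	PI4KAP2	chr22	20561000	20569000	+	pseudogene			
PI4KA	PI4KA	chr22	20594000	20602000	-	protein_coding	6.6	True	True
SERPIND1	SERPIND1	chr22	20627000	20635000	+	protein_coding	7.3	True	True
SNAP29	SNAP29	chr22	20660000	20668000	-	protein_coding	8.0	True	True
CRKL	CRKL	chr22	20693000	20701000	+	protein_coding	8.7	True	True
MIR1286	MIR1286	chr22	20726000	20734000	-	miRNA		True	
AIFM3	AIFM3	chr22	20759000	20767000	+	protein_coding	10.1	True	True
LZTR1	LZTR1	chr22	20792000	20800000	-	protein_coding	6.8	True	True
THAP7	THAP7	chr22	20825000	20833000	+	protein_coding	7.5	True	True
LINC00896	LINC00896	chr22	20858000	20866000	-	ncRNA			
RPS17P16	RPS17P16	chr22	20891000	20899000	+	pseudogene			
MIR4761	MIR4761	chr22	20924000	20932000	-	miRNA			
P2RX6	P2RX6	chr22	20957000	20965000	+	protein_coding	10.3	True	False
P2RX6P	P2RX6P	chr22	20990000	20998000	-	pseudogene			
SLC7A4	SLC7A4	chr22	21023000	21031000	+	protein_coding	3.1	False	
MTCO2P22	MTCO2P22	chr22	21056000	21064000	-	pseudogene			
LOC101927859	LOC101927859	chr22	21089000	21097000	+	protein_coding		False	
LINC01311	LINC01311	chr22	21122000	21130000	-	ncRNA			
HMGN1P34	HMGN1P34	chr22	21155000	21163000	+	pseudogene			
LRRC74B	LRRC74B	chr22	21188000	21196000	-	protein_coding		True	
RPL13AP17	RPL13AP17	chr22	21221000	21229000	+	pseudogene			
SNX18P1B	SNX18P1B	chr22	21254000	21262000	-	pseudogene			
MIR6816	MIR6816	chr22	21287000	21295000	+	miRNA			
DUXAP4	DUXAP4	chr22	21320000	21328000	-	pseudogene			
KRT8P46	KRT8P46	chr22	21353000	21361000	+	pseudogene			
LINC01637	LINC01637	chr22	21386000	21394000	-	ncRNA			
ACTG1P22	ACTG1P22	chr22	21419000	21427000	+	pseudogene			
HSPD1P8	HSPD1P8	chr22	21452000	21460000	-	pseudogene			
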