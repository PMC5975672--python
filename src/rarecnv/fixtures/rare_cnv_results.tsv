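patient_id	cytoband	chrom	start	end	type	size_kbp	copy_number	genes
5	4q24	4	104554264	105123728	internal_dup	569.464	3	TACR3
5	6p22.2	6	26019198	26227973	genic_dup	208.775	3	HIST1H3A;HIST1H4A;HIST1H4B;HIST1H3B;HIST1H2AB;HIST1H2BB;HIST1H3C;HIST1H1C;HFE;HIST1H4C;HIST1H1T;HIST1H2BC;HIST1H2AC;HIST1H1E;HIST1H2BD;HIST1H2BE;HIST1H4D;HIST1H3D;HIST1H2AD;HIST1H2BF;HIST1H4E;HIST1H2BG;HIST1H2AE;HIST1H3E
7	1q21.1	1	145625128	145927662	genic_del	302.534	1	RNF115;CD160;PDZK1;GPR89A;GPR89C;PDZK1P1
10	5q23.1	5	115247380	115683172	genic_dup	435.792	3	AP3S1;AQPEP;LOC644100;COMMD10
16	6p12.1	6	54138106	54277341	genic_dup	139.235	3	TINAG
18	12p13.33	12	173786	356461	genic_dup	182.675	3	IQSEC3;LOC574538;SLC6A12;SLC6A13
20	12q24.31	12	123357010	124310519	genic_dup	953.509	3	VPS37B;ABCB9;OGFOD2;ARL6IP4;PITPNM2;MIR4304;LOC100507091;MPHOSPH9;C12orf65;CDK2AP1;SBNO1;SETD8;RILPL2;SNRNP35;RILPL1;MIR3908;TMED2;DDX55;EIF2B1;GTF2H3;TCTN2;ATP6V0A2;DNAH10
20	19q13.32	19	47308130	47418258	genic_dup	110.128	3	SNAR-E;AP2S1
26	11q12.2	11	60408411	60465698	genic_del	57.287	1	LINC00301
31	10p15.1	10	6254055	6374584	internal_dup	120.529	3	PFKFB3;LOC399715
34	4q22.2	4	93875432	93988049	genic_del	112.617	1	GRID2
39	8q11.1q11.21	8	47398661	48407568	genic_dup	1008.907	3	LINC00293;LOC100287846;KIAA0146
40	14q24.2	14	73620299	73786493	genic_dup	166.194	3	PSEN1;PAPLN;NUMB
43	4q24	4	101476709	101668938	genic_del	192.229	1	EMCN-IT3
59	2q24.1	2	157170397	157315649	internal_dup	145.252	3	NR4A2;GPD2
59	6q26	6	163549870	163842358	genic_dup	292.488	3	PACRG;PACRG-AS1;DKFZp451B082;CAHM;QKI
59	9p22.2	9	16826417	16931236	internal_dup	104.819	3	BNC2
63	3q25.32	3	158198274	158256949	genic_del	58.675	1	RSRC1
63	10q26.3	10	134358785	134921135	genic_dup	562.35	4	INPP5A;NKX6-2;TTC40;LOC399829;GPR123
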