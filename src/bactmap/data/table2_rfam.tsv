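name	rfam_id	pred_start	pred_end	bit_score	strand	rnaseq	obs_start	obs_end	gene
FMN riboswitch	RF00050	66442	66279	111.60	-	observed	66438	66198	cg0083
cspA mRNA 5'-UTR	RF01766	186399	186766	60.19	+	observed	186328	186508	cg0215
TPP riboswitch	RF00059	742654	742547	63.54	-	observed	742651	742490	cg0825
ydaO-yuaA leader	RF00379	870027	869859	69.93	-	observed	870047	869853	cg0936
TPP riboswitch	RF00059	1127774	1127883	51.03	+	observed	1127765	1127874	cg1227
mini-ykkC RNA motif	RF01068	1131047	1131094	33.52	+	not_observed
TPP riboswitch	RF00059	1373213	1373103	55.87	-	observed	1373210	1373105	cg1476
SAM-IV riboswitch	RF00634	1374007	1374123	70.47	+	observed	1374005	1374139	cg1478
TPP riboswitch	RF00059	1544490	1544383	52.11	-	observed	1544485	1544390	cg1655
yybP-ykoY leader	RF00080	1550030	1550196	43.71	+	not_observed
yybP-ykoY leader	RF00080	2043157	2042989	49.13	-	observed	2043151	2042955	cg2157
TPP riboswitch	RF00059	2120271	2120383	62.55	+	observed	2120271	2120384	cg2236
mraW RNA motif	RF01746	2267021	2266916	56.64	-	observed	2266932	2266800	cg2377
ydaO-yuaA leader	RF00379	2292467	2292279	59.37	-	observed	2292509	2292267	cg2402
msiK RNA motif	RF01747	2582375	2582317	52.13	-	observed	2582404	2582315	cg2708
yybP-ykoY leader	RF00080	2649004	2648890	49.90	-	not_observed
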