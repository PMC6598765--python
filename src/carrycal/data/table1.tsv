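sample_id	protocol	ab_first	bsa	primary_count	spikein_count	carryover_count
pA_lohi_1	pA lo-hi	-	-	5913983	743	3455
pA_lohi_2	pA lo-hi	-	+	7748003	858	4988
pA_lohi_3	pA lo-hi	+	-	5202278	2288	16110
pA_lohi_4	pA lo-hi	+	+	5178086	1804	18759
pA_std_1	pA std	-	-	6013347	595	2462
pA_std_2	pA std	-	+	6005080	859	2295
pA_std_3	pA std	+	-	4104736	2624	21236
pA_std_4	pA std	+	+	3972820	2328	19245
pAG_lohi_1	pAG lo-hi	-	-	6999802	789	404
pAG_lohi_2	pAG lo-hi	-	+	6374939	642	467
pAG_lohi_3	pAG lo-hi	+	-	4140407	1565	1291
pAG_lohi_4	pAG lo-hi	+	+	4058693	2382	5289
pAG_std_1	pAG std	-	-	7514127	308	567
pAG_std_2	pAG std	-	+	5935592	355	125
pAG_std_3	pAG std	+	-	4594153	1271	555
pAG_std_4	pAG std	+	+	5379610	2509	1353
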