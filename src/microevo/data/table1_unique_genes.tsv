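gene_id	size_aa	most_ancestral_detection	homolog_in_partner	predicted_dna_binding	median_coverage
pclt_cds_11	69	Since node 5	None	Yes	704
pclt_cds_308	181	Since node 2	pqer_ncRNA_47	No	986
pclt_cds_350	121	Since node 9	Intergenic	Yes	57
pclt_cds_376	145	Since node 5	3'UTR pqer_cds_371	Yes	454
pclt_cds_725	104	None	None	Yes	46
pclt_cds_870	205	Since node 2	None	Yes	2027
pclt_cds_995	149	Since node 5	5'UTR pqer_cds_981	Yes	13
pclt_cds_1081	125	Since node 8	5'UTR pqer_cds_1061	Yes	12090
pclt_cds_1084	114	Since node 8	Intergenic	Yes	130
pqer_cds_6	76	Since node 8	None	Yes	311
pqer_cds_13	117	Since node 5	Intergenic	Yes	99
pqer_cds_17	82	Since node 2	Intergenic	Yes	482
pqer_cds_53	85	Since node 8	Intergenic	Yes	48
pqer_cds_143	93	Since node 8	Anti 5'UTR pclt_cds_146	Yes	177
pqer_cds_151	71	Since node 9	Intergenic	Yes	21
pqer_cds_203	101	Since node 8	Antisense pclt_cds_206	Yes	528
pqer_cds_350	94	None	None	No	160
pqer_cds_474	74	Since node 9	Intergenic	Yes	114
pqer_cds_486	146	Since node 2	3'UTR pclt_cds_499	Yes	71
pqer_cds_665	114	None	None	Yes	1955
pqer_cds_673	383	None	None	Yes	656
pqer_cds_685	124	Since node 8	Alternative frame pclt_cds_685	No	117
pqer_cds_736	121	Since node 9	Intergenic	Yes	70
pqer_cds_875	136	None	None	No	2050
pqer_cds_876	74	Since node 2	None	No	1695
pqer_cds_877	78	None	None	Yes	320
pqer_cds_878	224	None	None	Yes	231
pqer_cds_1061	152	Since node 8	Alternative frame pclt_cds_1081	Yes	14186
pqer_cds_1178	84	Since node 9	Anti 5'UTR pclt_cds_1203	Yes	170
pqer_cds_1183	158	Since node 2	None	Yes	198
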