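virus_id	classification	amc_rna	amc_rna_pass	ad_rna	ad_rna_pass	amc_dna	amc_dna_pass	ad_dna	ad_dna_pass
NC_022518.1_HERV_K113	ssRNA-RT	1289	True	2242	True	3586	True	4698	True
NC_001806.1_Human_herpesvirus_1	dsDNA	162	False	327	False	192	True	183	True
NC_001798.1_Human_herpesvirus_2	dsDNA	12806	True	28052	True	1403	True	1589	False
NC_007605.1_Human_herpesvirus_4	dsDNA	137	False	234	True	200	True	178	True
NC_000898.1_Human_herpesvirus_6B	dsDNA	521	False	1476	True	2411	True	2627	True
NC_012959.1_Human_adenovirus_54	dsDNA	273	True	440	True	14	False	10	False
NC_009823.1_Hepatitis_C_virus_type_2	+ssRNA	5492	False	15501	False	19181	True	22028	False
HPV6REF.1_Human_papillomavirus_6	dsDNA	82	False	140	False	151	False	218	True
HPV9REF.1_Human_papillomavirus_9	dsDNA	121	False	405	False	94	True	112	False
HPV72REF.1_Human_papillomavirus_72	dsDNA	334	True	692	False	22	False	33	False
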