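name	pattern	promoters_in_query	promoters_observed	total_observed	avg_per_promoter	expected_printed	enrichment_printed	pvalue_printed
AGCBOXNPGLB	AGCCGCC	23	1	1	1.00	0.0575	17.39	0.0041
RAV1AAT	CAACA	23	22	93	4.23	31.02	3.00	0.0337
GT1GMSCAM4	GAAAAA	23	22	72	3.27	28.98	2.48	0.0327
CTCTT	CTCTT	23	23	77	3.35	NA	2.43	0.0325
SURE2STPAT21	AATACAAAA	23	3	3	1.00	1.58	1.90	0.0194
AuxRe1	TGTCTC	23	6	8	1.33	4.77	1.68	0.0293
WBBOXPCWRKY1	TTTGACY	23	7	8	1.14	NA	1.41	NA
MYCATERD22	CACATG	23	6	7	1.17	4.53	1.54	NA
MYCATERD1	CATGTG	23	7	7	1.00	4.67	1.50	NA
ABRE	ACGTGTC	23	1	1	1.00	0.69	1.45	NA
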