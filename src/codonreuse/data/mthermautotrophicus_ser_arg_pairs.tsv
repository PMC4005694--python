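# Published Ser/Arg codon-pair co-occurrence and expected counts for the
# Methanothermobacter thermautotrophicus deltaH genome (NC_000916.1),
# counted over all pairs of codons found in the whole genome.
# Expected counts are rounded to integers as published.
# Note: the published Arg2 AGA-AGA count is internally inconsistent with its
# expected count and percent deviation; values are transcribed verbatim.
family	codon_i	codon_j	count	expected
Ser4	TCA	TCA	3680	3505
Ser4	TCA	TCC	2262	2268
Ser4	TCA	TCG	480	515
Ser4	TCA	TCT	815	928
Ser4	TCC	TCA	2149	2268
Ser4	TCC	TCC	1474	1468
Ser4	TCC	TCG	320	334
Ser4	TCC	TCT	616	600
Ser4	TCG	TCA	456	515
Ser4	TCG	TCC	313	334
Ser4	TCG	TCG	76	76
Ser4	TCG	TCT	132	136
Ser4	TCT	TCA	903	928
Ser4	TCT	TCC	586	600
Ser4	TCT	TCG	142	136
Ser4	TCT	TCT	300	246
Ser2	AGC	AGC	1149	982
Ser2	AGC	AGT	718	655
Ser2	AGT	AGC	677	655
Ser2	AGT	AGT	513	437
Arg4	CGA	CGA	16	13
Arg4	CGA	CGC	30	34
Arg4	CGA	CGG	31	47
Arg4	CGA	CGT	42	47
Arg4	CGC	CGA	30	34
Arg4	CGC	CGC	109	84
Arg4	CGC	CGG	132	118
Arg4	CGC	CGT	114	118
Arg4	CGG	CGA	27	47
Arg4	CGG	CGC	135	118
Arg4	CGG	CGG	214	165
Arg4	CGG	CGT	149	165
Arg4	CGT	CGA	51	47
Arg4	CGT	CGC	133	118
Arg4	CGT	CGG	149	165
Arg4	CGT	CGT	172	165
Arg2	AGA	AGA	1346	1092
Arg2	AGA	AGG	3452	3702
Arg2	AGG	AGA	3326	3702
Arg2	AGG	AGG	12842	12546
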