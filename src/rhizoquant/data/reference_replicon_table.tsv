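# Published replicon distribution of proteins detected in Rlv UPM791 vegetative
# cells and pea/lentil bacteroids. genome_total_printed: the published genome
# column total (7318) differs from the sum of per-replicon counts (7571); the
# printed percentages match the 7318 denominator, so that value is used as the
# supplied denominator rather than silently correcting the table.
replicon	genome_count	genome_pct	vegetative_count	vegetative_pct	pea_count	pea_pct	pea_host_specific	lentil_count	lentil_pct	lentil_host_specific
Chromosome	4587	62.7	1154	87.1	901	81.6	12	891	85.3	13
pRlvA	1246	17.0	62	4.7	50	4.5	4	42	4.0	8
pRlvB	588	8.0	44	3.3	50	4.5	3	35	3.3	2
pRlvC	366	5.0	10	0.7	68	6.2	7	50	4.8	1
pRlvD	239	3.3	8	0.6	3	0.3	0	4	0.4	0
pRlvE	545	7.4	46	3.5	32	2.9	2	22	2.1	1
Total	7318		1324		1104	28	1044		25
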