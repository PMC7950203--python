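# Published iTRAQ comparative analysis of Rlv UPM791 pea and lentil bacteroid
# proteomes: all 36 proteins listed with a significant pea/lentil ratio
# (28 pea-overrepresented including the 2.00 boundary case, 8 lentil-
# overrepresented including the 0.50 boundary case).
protein_id	replicon	description	itraq_pl_ratio
RLV_1136	pRlvA	ornithine carbamoyltransferase	2.62
RLV_1140	pRlvA	lysine decarboxylase, inducible	2.60
RLV_1141	pRlvA	ornithine decarboxylase, inducible	2.20
RLV_1384	pRlvB	universal stress protein	2.10
RLV_1399	pRlvB	molecular chaperone Hsp20	2.00
RLV_1404	pRlvB	phosphoketolase	2.24
RLV_1805	pRlvC	hypothetical protein	2.45
RLV_1815A	pRlvC	putative amino-acid racemase	2.06
RLV_1821	pRlvC	OsmC-like protein	2.23
RLV_1826	pRlvC	redoxin	2.29
RLV_1843A	pRlvC	cytochrome C biogenesis redoxin protein	3.22
RLV_1844	pRlvC	diaminobutyrate aminotransferase	2.41
RLV_1845	pRlvC	putative urea amidolyase	2.86
RLV_1846	pRlvC	D-alanine--D-alanine ligase	3.77
RLV_1848	pRlvC	glutamyl-tRNA reductase	2.88
RLV_1849	pRlvC	putative urea amidolyase	2.66
RLV_1887	pRlvC	putative glutamate dehydrogenase	2.35
RLV_1889	pRlvC	TlpA-like family protein	2.12
RLV_1961	pRlvC	uptake hydrogenase large subunit HupL	2.42
RLV_1979	pRlvC	isocitrate dehydrogenase	2.39
RLV_4347	Chromosome	universal stress protein	3.02
RLV_4576A	Chromosome	dimethylmenaquinone methyltransferase	2.34
RLV_4577	Chromosome	universal stress protein UspA	2.16
RLV_4675	Chromosome	nitrogen regulatory protein P-II 1	2.16
RLV_5449	Chromosome	GntR family transcriptional regulator	2.66
RLV_7044	Chromosome	phosphoenolpyruvate carboxykinase [ATP]	2.24
RLV_7109	Chromosome	NAD-dependent succinate-semialdehyde dehydrogenase	3.24
RLV_7281	Chromosome	YciF stress-response ferritin-like protein	2.04
RLV_502	pRlvA	putative small heat shock protein	0.36
RLV_817	pRlvA	molecular chaperone Hsp20	0.17
RLV_818	pRlvA	putative small heat shock protein	0.45
RLV_1833	pRlvC	transmembrane nitrogen fixation cation transport protein FixI	0.34
RLV_1892	pRlvC	nitrogen fixation FixC protein	0.42
RLV_1894	pRlvC	NifA transcriptional regulator	0.39
RLV_1896	pRlvC	SAM-dependent methyltransferase	0.39
RLV_5494	Chromosome	acetolactate synthase	0.50
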