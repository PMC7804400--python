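# Worked-example candidate table: transcribed-marker candidates at Parkinson's
# disease GWAS risk loci (lead/proxy pairs with LD and annotation metadata).
# The thirteen markers that survive selection carry published r2/D' values.
# SYNTHETIC fields, reconstructed to reproduce the described exclusions only:
#   - rs749670 r2/D' (its assay failed calibration; replaced by rs749671),
#   - the five inversion-locus proxies (placeholder IDs rsINV17q001..005 --
#     the source selection does not name them individually),
#   - rs2273596 and rs3783640 LD values, and lead/locus labels for excluded rows.
lead_snp	proxy_snp	gene	r2	dprime	annotation	locus_id	is_secondary_signal	in_inversion_region	isoform_restricted	assay_failed	technology
rs14235	rs14235	BCKDK	1	1	synonymous	BCKDK_ZNF646	False	False	False	False	TaqMan
rs14235	rs749671	ZNF646	0.8	0.9	synonymous	BCKDK_ZNF646	False	False	False	False	TaqMan
rs14235	rs749670	ZNF646	0.95	0.97	synonymous	BCKDK_ZNF646	False	False	False	True	KASP
rs199347	rs199355	GPNMB	0.93	0.98	synonymous	GPNMB	False	False	False	False	TaqMan
rs823118	rs708723	RAB7L1	0.95	0.98	3'UTR	PARK16	False	False	False	False	TaqMan
rs823118	rs951366	NUCKS1	0.72	-0.98	3'UTR	PARK16	False	False	False	False	KASP
rs1474055	rs76179989	STK39	0.94	0.99	5'UTR	STK39	False	False	False	False	TaqMan
rs8118008	rs58241213	LZTS3	0.77	0.89	5'UTR	LZTS3	False	False	False	False	KASP
rs10799596	rs4649383	SIPA1L2	0.64	-0.99	synonymous	SIPA1L2	False	False	False	False	KASP
rs11158026	rs28481699	WDHD1	0.71	0.86	3'UTR	GCH1_WDHD1	False	False	False	False	TaqMan
rs12637471	rs2270968	MCCC1	0.71	-1	missense	MCCC1	False	False	False	False	TaqMan
rs34311866	rs34311866	TMEM175	1	1	missense	TMEM175	False	False	False	False	TaqMan
rs34884217	rs34884217	TMEM175	1	1	missense	TMEM175	True	False	False	False	TaqMan
rs35749011	rs2230288	GBA	0.69	0.83	missense	GBA	False	False	False	False	KASP
rs11158026	rs11158026	GCH1	1	1	intronic	GCH1_WDHD1	False	False	False	False
rs11158026	rs3783640	GCH1	0.95	0.97	intronic	GCH1_WDHD1	False	False	False	False
rs356182	rs356165	SNCA	0.76	0.9	3'UTR	SNCA	False	False	True	False
rs1555399	rs2273596	TMEM229B	0.8	0.9	synonymous	TMEM229B	False	False	False	False	TaqMan
rs17649553	rs17649553	MAPT	0.9	0.95	intronic	CHR17Q21	False	True	False	False
rs17649553	rsINV17q001	CRHR1	0.92	0.96	missense	CHR17Q21	False	True	False	False
rs17649553	rsINV17q002	SPPL2C	0.91	0.95	missense	CHR17Q21	False	True	False	False
rs17649553	rsINV17q003	MAPT	0.9	0.95	synonymous	CHR17Q21	False	True	False	False
rs17649553	rsINV17q004	STH	0.89	0.94	synonymous	CHR17Q21	False	True	False	False
rs17649553	rsINV17q005	KANSL1	0.88	0.94	3'UTR	CHR17Q21	False	True	False	False
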