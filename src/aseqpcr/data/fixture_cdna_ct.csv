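# SYNTHETIC cDNA Ct observations for the low-expression stage of the packaged
# worked example. rs2273596 (TMEM229B) reproduces the described exclusion:
# more than half of its cDNA samples exceed the Ct 36 cut-off, indicating a
# very low expression level of the gene in the target tissue. rs28481699
# (WDHD1) shows a normally expressed assay for contrast. The token
# "Undetermined" marks a reaction censored at the cycle limit.
proxy_snp,sample_id,ct
rs2273596,S01,37.4
rs2273596,S02,38.1
rs2273596,S03,36.9
rs2273596,S04,Undetermined
rs2273596,S05,37.8
rs2273596,S06,36.2
rs2273596,S07,33.5
rs2273596,S08,34.1
rs2273596,S09,33.8
rs2273596,S10,34.6
rs28481699,S01,27.2
rs28481699,S02,27.8
rs28481699,S03,26.9
rs28481699,S04,28.1
rs28481699,S05,27.5
rs28481699,S06,27.3
rs28481699,S07,28.0
rs28481699,S08,27.1
rs28481699,S09,27.7
rs28481699,S10,27.4
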