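time	gene_a	fc_a	padj_a	gene_b	fc_b	padj_b	sirna_fc	sirna_padj
6h	AT2G22080	4.75	0.05	AT2G22090	-1.41	1.0	2.0	0.05
2d	AT5G20020	2.58	0.05	AT5G20030	-2.17	0.05	2.0	0.05
2d	AT3G11830	2.86	0.05	AT3G11840	-2.9	0.05	2.0	0.05
2d	AT1G03090	-2.5	0.05	AT1G03100	2.47	0.05	2.0	0.05
2d	AT1G72030	-2.3	0.05	AT1G72040	2.44	0.05	2.0	0.05
2d	AT2G40420	-2.3	0.05	AT2G40430	2.32	0.05	2.0	0.05
2d	AT5G52440	-1.7	1.0	AT5G52450	2.9	0.05	2.0	0.05
2d	AT3G16800	-1.4	1.0	AT3G16810	5.5	0.05	2.0	0.05
2d	AT2G22080	3.13	0.05	AT2G22090	-1.51	1.0	2.0	0.05
2d	AT1G13930	4.53	0.05	AT1G13940	-1.31	1.0	2.0	0.05
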