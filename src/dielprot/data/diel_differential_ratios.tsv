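accession	name	ratio_rep1	sdgeo_rep1	n_rep1	sig_rep1	ratio_rep2	sdgeo_rep2	n_rep2	sig_rep2
ARTHROv3_190004	Phosphoenolpyruvate synthase	0.43	1.22	3	1	0.55	1.30	4	1
ARTHROv3_1130101	Conserved hypothetical protein	0.43	1.09	2	1	0.53	1.45	4	1
ARTHROv3_930103	Photosystem I P700 chlorophyll a apoprotein A2 (PsaB)	0.52	1.68	7	1	0.52	1.39	8	1
ARTHROv3_1050021	Isocitrate dehydrogenase [NADP]	0.52	1.04	2	1	0.55	1.13	2	0
ARTHROv3_1620020	Photosystem II P680 chlorophyll A apoprotein (CP-47 protein)	0.66	1.56	9	1	0.42	1.65	5	1
ARTHROv3_210030	Photosystem II 12 kDa extrinsic protein precursor (PSII-U)	0.51	1.37	5	1	0.67	1.23	3	1
ARTHROv3_930104	Photosystem I P700 chlorophyll a apoprotein A1 (PsaA)	0.66	1.45	7	1	0.59	1.76	8	1
ARTHROv3_810100	Hypothetical protein	0.62	1.24	2	0	0.67	1.04	2	1
ARTHROv3_6720001	Photosystem Q(B) protein 1 precursor (Photosystem II protein D1 1)	0.72	1.31	4	1	0.61	1.39	6	1
ARTHROv3_1210006	Photosystem II CP43 protein (PSII D2 protein)	0.74	1.27	5	1	0.53	1.40	4	0
ARTHROv3_1620014	Acyl carrier protein	0.76	1.24	2	0	0.60	1.08	4	1
ARTHROv3_630063	ATP synthase B chain (Subunit I)	0.66	1.30	5	1	0.73	1.36	3	0
ARTHROv3_810066	Putative Calvin cycle regulator CP12-like protein	0.72	1.44	4	0	0.70	1.31	5	1
ARTHROv3_630062	ATP synthase delta chain; ATP synthase F1. delta subunit	0.65	1.18	4	1	0.81	1.27	7	0
ARTHROv3_810107	Phosphoenolpyruvate synthase (part 2)	0.88	1.84	16	1	0.67	1.71	16	1
ARTHROv3_2890001	Protein chain elongation factor EF-G. GTP-binding	0.76	1.22	8	1	0.79	1.31	6	0
ARTHROv3_760043	Conserved hypothetical protein	0.81	1.14	5	1	0.78	1.14	6	1
ARTHROv3_1100012	Phycobilisome 32 kDa linker polypeptide. phycocyanin-associated. rod 1	1.13	1.31	10	0	1.30	1.36	14	1
ARTHROv3_5910003	Allophycocyanin alpha subunit	1.34	1.33	13	1	1.14	NA	10	0
ARTHROv3_1400046	Inositol-5-monophosphate dehydrogenase	1.49	1.39	4	1	1.15	1.51	4	0
ARTHROv3_6740003	30S ribosomal protein S1	1.41	1.65	7	0	1.33	1.22	8	1
ARTHROv3_1350003	Hypothetical protein	1.28	1.25	5	0	1.43	1.11	5	1
ARTHROv3_680013	Hypothetical protein	1.37	1.26	7	1	1.41	1.26	8	1
ARTHROv3_1100014	Phycobilisome 8.9 kDa linker polypeptide. phycocyanin-associated. rod	1.37	1.28	6	1	1.42	NA	9	0
ARTHROv3_1610009	Adenylosuccinate synthetase. IMP-aspartate ligase	1.37	1.12	2	1	1.57	1.01	2	1
ARTHROv3_1280008	Allophycocyanin beta-18 subunit	1.51	1.98	4	0	1.49	1.35	6	1
ARTHROv3_860009	30S ribosomal protein S6	1.34	1.24	4	0	1.71	1.64	6	1
ARTHROv3_1540080	30S ribosomal subunit protein S4	1.81	1.11	2	1	1.55	1.34	4	0
ARTHROv3_310008	30S ribosomal subunit protein S21	1.68	1.24	4	1	1.89	1.02	2	1
ARTHROv3_870040	Glycine-rich RNA-binding protein. rbp-like	3.43	2.89	7	0	4.12	2.36	5	1
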