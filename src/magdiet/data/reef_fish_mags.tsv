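mag_id	diet	phylum	class	order	family	genus	species	completeness	contamination	coverage	ani_or_red	neighbor_accession
H1N1.001	piscivorous	Proteobacteria	Gammaproteobacteria	Enterobacterales	Vibrionaceae	Photobacterium	aphoticum	97.58	2.55	94.31	95.41	GCF_001029435.1
H1N1.003	piscivorous	Proteobacteria	Gammaproteobacteria	Pseudomonadales	Alcanivoracaceae	Alcanivorax	sp.	100	0.74	61.69	97.91	GCA_002706085.1
H1N1.005	piscivorous	Proteobacteria	Alphaproteobacteria	Parvibaculales	Phaeomarinobacteraceae	Phaeomarinobacter	sp.	86.52	5.77	35.76	79.02	GCF_000689395.1
H1N1.006	piscivorous	Proteobacteria	Alphaproteobacteria	Rhodobacterales	Rhodobacteraceae	Phaeobacter	italicus	99.66	6.79	35.06	98.07	GCF_001258055.1
H1N1.007	piscivorous	Proteobacteria	Alphaproteobacteria	Rhodospirillales	Thalassospiraceae	Thalassospira	sp.	100	1	33.33	85.04	GCF_003326795.1
H1N1.009	piscivorous	Bacteroidota	Bacteroidia	Cytophagales	Cyclobacteriaceae	Fabibacter	pacificus	98.73	2.89	31.61	96.83	GCF_900111145.1
H1N1.010	piscivorous	Proteobacteria	Gammaproteobacteria	Enterobacterales	Vibrionaceae	Vibrio	fortis	74.03	9.2	41.62	96.01	GCF_000695685.1
H1N1.011	piscivorous	Patescibacteria	Gracilibacteria	UBA1369	GCA-2718715	-	-	73.06	0.93	18	76.01	GCA_002718715.1
H1N1.012	piscivorous	Proteobacteria	Alphaproteobacteria	Rhodobacterales	Rhodobacteraceae	Ruegeria	sp.	98.27	3.69	16.12	RED, 0.98	n/a
H1N1.015	piscivorous	Bacteroidota	Bacteroidia	Cytophagales	Cyclobacteriaceae	Fabibacter	spongicola	98.01	0.6	12.06	96.92	GCF_001592965.1
H1N1.018	piscivorous	Proteobacteria	Alphaproteobacteria	Minwuiales	Minwuiaceae	Minwuia	sp.	98.91	3.77	13.26	79.34	GCF_002924445.1
H1N1.021	piscivorous	Proteobacteria	Gammaproteobacteria	Pseudomonadales	Porticoccaceae	Porticoccus	sp.	89.33	3.83	7.95	95.8	GCA_006226995.1
H1N1.022	piscivorous	Proteobacteria	Gammaproteobacteria	Enterobacterales	Alteromonadaceae	Alteromonas	sp.	92.49	9.21	7.86	90.14	GCF_003731635.1
H1N1.025	piscivorous	Proteobacteria	Gammaproteobacteria	Enterobacterales	Alteromonadaceae	Pseudoalteromonas	spongiae	70.69	6.03	9.77	96.51	GCF_000238255.3
H1N1.026	piscivorous	Proteobacteria	Alphaproteobacteria	Sphingomonadales	Sphingomonadaceae	Erythrobacter	flavus	94.33	0.86	8.16	97.62	GCF_002237615.1
H1N1.028	piscivorous	Proteobacteria	Alphaproteobacteria	Caulobacterales	Maricaulaceae	Maricaulis	sp.	93.44	1.68	6.04	81.73	GCF_005871165.1
H1N1.030	piscivorous	Bacteroidota	Bacteroidia	Cytophagales	Flammeovirgaceae	Sediminitomix	sp.	93.49	8.17	4.71	80.04	GCF_003149185.1
H1N1.033	piscivorous	Proteobacteria	Alphaproteobacteria	UBA8366	GCA-2696645	GRI0909	sp.	87.3	12.75	4.31	80.5	GCF_004005845.1
T4LTN.001	herbivorous	Bacteroidota	Bacteroidia	Bacteroidales	Bacteroidaceae	Bacteroides	sp.	98.51	0.5	240.58	98.79	GCA_002471185.1
T4LTN.002	herbivorous	Bacteroidota	Bacteroidia	Bacteroidales	Paludibacteraceae	-	-	85.3	5.67	45.25	RED, 0.86	n/a
T4LTN.003	herbivorous	Proteobacteria	Gammaproteobacteria	Enterobacterales	Vibrionaceae	Vibrio	owensii	92.93	1.51	51.4	96.86	GCF_000817815.1
T4LTN.004	herbivorous	Proteobacteria	Gammaproteobacteria	Enterobacterales	Shewanellaceae	Shewanella	sp.	94.4	3.15	39.3	84.16	GCF_003353085.1
T4LTN.005	herbivorous	Bacteroidota	Bacteroidia	Bacteroidales	Tannerellaceae	-	sp.	96.92	7.31	34.71	79.39	GCF_000969825.1
T4LTN.006	herbivorous	Firmicutes	Clostridia	Lachnospirales	Lachnospiraceae	-	sp.	99.11	4.83	21.97	80.86	GCF_000733755.1
T4LTN.007	herbivorous	Proteobacteria	Gammaproteobacteria	Enterobacterales	Alteromonadaceae	-	-	91.46	10.06	33.35	77.83	GCF_002954545.1
T4LTN.009	herbivorous	Proteobacteria	Gammaproteobacteria	Enterobacterales	Alteromonadaceae	-	-	92.4	3.7	17.73	78.04	GCF_002954545.1
T4LTN.010	herbivorous	Spirochaetota	Spirochaetia	Sphaerochaetales	Sphaerochaetaceae	-	-	100	2.3	21.93	77.22	GCA_001604275.1
T4LTN.011	herbivorous	Bacteroidota	Bacteroidia	Bacteroidales	UBA1402	UBA8389	sp.	100	2.02	18.54	76.81	GCA_003506275.1
T4LTN.012	herbivorous	Proteobacteria	Gammaproteobacteria	Enterobacterales	Vibrionaceae	Enterovibrio	sp.	97.84	0.9	17.66	82.02	GCA_001310415.1
T4LTN.014.2	herbivorous	Firmicutes	Bacilli	RF39	CAG-822	UBA5364	sp.	96.63	0.61	19.86	76.06	GCA_002410935.1
T4LTN.014.3	herbivorous	Patescibacteria	Gracilibacteria	BD1-5	UBA6164	MAAV01	sp.	83.15	1.69	11.87	77.15	GCA_004563595.1
T4LTN.015	herbivorous	Firmicutes	Clostridia	Oscillospirales	Ruminococcaceae	UMGS363	sp.	97.32	6.64	22.67	RED, 0.92	n/a
T4LTN.016	herbivorous	Proteobacteria	Gammaproteobacteria	Pseudomonadales	Saccharospirillaceae	Oleispira	sp.	87.84	3.6	16.05	RED, 0.96	n/a
T4LTN.017	herbivorous	Firmicutes	Clostridia	Oscillospirales	Ruminococcaceae	-	-	99.32	0.91	9.67	RED, 0.79	n/a
T4LTN.022	herbivorous	Proteobacteria	Alphaproteobacteria	Sphingomonadales	Sphingomonadaceae	Erythrobacter	flavus	95.9	7.03	5.72	97.4	GCF_002237615.1
T4LTN.023	herbivorous	Bacteroidota	Bacteroidia	Bacteroidales	P3	-	-	86.31	2.89	5.4	RED, 0.90	n/a
Tr3LTN.002	invertivorous	Proteobacteria	Gammaproteobacteria	Enterobacterales	Shewanellaceae	Shewanella	sp.	98.87	1.08	74.15	84.49	GCF_003353085.1
Tr3LTN.005	invertivorous	Proteobacteria	Alphaproteobacteria	Rhodobacterales	Rhodobacteraceae	Epibacterium	sp.	98.94	3.55	11.73	96.78	GCF_001681715.1
Tr3LTN.006	invertivorous	Proteobacteria	Gammaproteobacteria	Psuedomonadales	Cellvibrionaceae	GCA-2707785	sp.	95.52	1.92	26.73	76.39	GCA_002707785.1
Tr3LTN.008	invertivorous	Campylobacterota	Campylobacteria	Campylobacterales	Arcobacteraceae	UBA4036	sp.	99.19	2.37	11.66	77.9	GCA_002382325.1
Tr3LTN.016	invertivorous	Firmicutes	Bacilli	-	-	-	-	84.8	7.11	5.09	RED, 0.70	n/a
Tr3LTN.017	invertivorous	Proteobacteria	Alphaproteobacteria	UBA1280	UBA12223	UBA12223	-	81.93	2.99	7.53	81.5	GCA_002937495.1
Tr3LTN.026	invertivorous	Bdellovibrionota	Bacteriovoracia	Bacteriovoracales	Bacteriovoracaceae	-	-	70.65	4.1	4.87	RED, 0.78	n/a
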