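study	trait	chrom	pos_mb_start	pos_mb_end	candidate_gene	fdr_flag	published
this_study	Plant height (cm)	Pv01	6.13	6.13	Phvul.001G054800	0	0
this_study	Growth habit	Pv01	6.28	6.28	Phvul.001G055600	1	0
this_study	Biomass (kg)	Pv01	6.49	6.49	Phvul.001G057100	0	0
pub_R18	Lodging score	Pv01	13.76	13.76	Phvul.001G087900	0	1
pub_R18	Growth habit	Pv01	13.76	13.76	Phvul.001G087900	0	1
pub_47	Days to flowering	Pv01	13.76	13.76	Phvul.001G087900	0	1
this_study	Days to flowering	Pv01	13.45	15.36	Phvul.001G087900	1	0
pub_53	Root rot damage	Pv01	23.92	23.92		0	1
pub_52	Days to flower	Pv01	27.68	27.68		0	1
pub_53	Root rot damage	Pv01	33.03	33.03		0	1
this_study	Halo blight damage score	Pv01	36.72	36.72	Phvul.001G132516	0	0
pub_53	Root rot damage	Pv01	37.20	37.20		0	1
this_study	Plant height (cm)	Pv01	38.74	38.74	Phvul.001G143800	0	0
pub_53	Root rot damage	Pv01	40.20	40.20		0	1
this_study	Growth habit	Pv01	42.17	42.17	Phvul.001G167200	1	0
this_study	Seed yield	Pv01	42.23	42.23	Phvul.001G167200	1	0
pub_47	Growth habit	Pv01	42.23	42.23	Phvul.001G167200	0	1
this_study	Biomass (kg)	Pv01	42.27	42.27	Phvul.001G167200	0	0
pub_07	Growth habit	Pv01	44.80	44.80	Phvul.001G189200	0	1
pub_47	Growth habit	Pv01	44.80	44.80	Phvul.001G192200	0	1
pub_49	Days to flowering	Pv01	47.07	47.07	Phvul.001G214500	0	1
pub_59	Days to flowering	Pv01	48.86	48.86		0	1
pub_59	Days to flowering	Pv01	49.65	49.65		0	1
this_study	Halo blight damage score	Pv02	16.17	16.17	Phvul.002G091900	0	0
this_study	Seed weight	Pv02	30.38	30.38	Phvul.002G150600	1	0
pub_52	Days to flowering	Pv02	38.07	38.07		0	1
pub_74	Halo blight damage score	Pv02	49.08	49.08	Phvul.002G326200	0	1
this_study	Harvest index (%)	Pv03	2.16	2.16	Phvul.003G023000	1	0
this_study	Seed weight	Pv03	4.40	4.40	Phvul.003G039900	1	0
this_study	Days to maturity	Pv03	15.75	15.75		0	0
this_study	Days to maturity	Pv03	32.04	32.04	Phvul.003G128400	0	0
this_study	Harvest index (%)	Pv03	36.82	36.82	Phvul.003G153100	0	0
this_study	Days to maturity	Pv03	36.83	36.83	Phvul.003G153100	0	0
pub_26	Seed yield	Pv03	37.60	37.60	Phvul.001G136600	0	1
pub_52	Days to flowering	Pv03	40.27	40.27		0	1
pub_52	Days to flowering	Pv03	41.09	41.09		0	1
pub_26	Harvest index (%)	Pv03	46.70	46.70	Phvul.003G233400	0	1
pub_26	Harvest index (%)	Pv03	47.17	47.17	Phvul.003G237900	0	1
pub_52	Days to flower	Pv03	47.35	47.35		0	1
pub_R18	Seed yield	Pv03	49.28	50.33	Phvul.003G253700	0	1
pub_52	Days to flowering and days to maturity	Pv03	51.48	51.48		0	1
pub_52	Days to flowering and days to maturity	Pv03	52.32	52.32		0	1
pub_52	Days to flowering and days to maturity	Pv03	52.60	52.60		0	1
pub_74	Halo blight damage score	Pv04	0.55	1.899	Phvul.004G007600	0	1
pub_47	Days to maturity	Pv04	1.94	1.94	Phvul.004G011400	0	1
this_study	Lodging score	Pv04	2.87	2.87	Phvul.004G025600	1	0
pub_47	Growth habit indeterminate	Pv04	3.20	3.20	Phvul.004G027800	0	1
companion_2020	Halo blight damage score	Pv04	6.79	6.79	Phvul.004G051500	0	0
pub_59	Days to flowering	Pv04	16.37	16.37		0	1
pub_59	Days to flowering	Pv04	36.88	36.88		0	1
pub_74	Halo blight damage score	Pv04	46.20	46.20	Phvul.004G158000	0	1
pub_52	Days to flowering and days to maturity	Pv04	46.33	46.33		0	1
pub_52	Days to flowering and days to maturity	Pv04	47.06	47.06		0	1
this_study	Halo blight damage score	Pv05	13.25	13.25	Phvul.005G074200	0	0
pub_74	Halo blight damage score	Pv05	39.00	39.00	Phvul.005G162500	0	1
pub_53	Root rot damage	Pv06	0.57	0.57		0	1
pub_53	Root rot damage	Pv06	5.75	5.75		0	1
pub_53	Root rot damage	Pv06	6.89	6.89		0	1
pub_53	Root rot damage	Pv06	8.16	8.16	Phvul.006G017211	0	1
pub_53	Root rot damage	Pv06	12.20	12.20		0	1
pub_53	Root rot damage	Pv06	17.85	17.85		0	1
this_study	Plant height (cm)	Pv06	20.89	20.89	Phvul.006G098300	0	0
pub_47	Growth habit indeterminate	Pv06	29.92	29.92	Phvul.006G203400	0	1
pub_59	Days to flowering	Pv06	31.60	31.60		0	1
this_study	Days to maturity	Pv07	1.15	1.15	Phvul.007G017000	0	0
pub_47	Growth habit indeterminate	Pv07	34.12	34.12	Phvul.007G246700	0	1
pub_47	Lodging score	Pv07	34.20	34.20	Phvul.007G218900	0	1
this_study	Lodging score	Pv07	33.60	34.51	Phvul.007G218900	1	0
pub_47	Plant height (cm)	Pv07	34.20	34.20	Phvul.007G218900	0	1
pub_47	Growth habit indeterminate	Pv07	34.20	34.20	Phvul.007G218900	0	1
this_study	Biomass (kg)	Pv07	35.74	35.74	Phvul.007G233700	0	0
pub_47	Seed weight	Pv08	1.10	1.10	Phvul.008G013300	0	1
this_study	Root rot damage score	Pv08	1.34	1.34		0	0
pub_59	Days to flowering	Pv08	4.93	4.93		0	1
pub_69	Biomass (kg)	Pv08	6.86	6.86	Phvul.008G073000	0	1
pub_69	Biomass (kg)	Pv08	7.60	7.60	Phvul.008G078200	0	1
pub_53	Root rot damage	Pv08	15.26	15.26		0	1
pub_53	Root rot damage	Pv08	17.72	17.72		0	1
pub_52	Days to flowering and days to maturity	Pv08	24.95	24.95		0	1
pub_59	Days to flowering	Pv08	26.40	26.40		0	1
pub_74	Halo blight damage score	Pv08	61.34	61.34	Phvul.008G268700	0	1
this_study	Root rot damage score	Pv08	61.98	61.98	Phvul.008G277352	0	0
this_study	Halo blight damage score	Pv09	5.42	5.42	Phvul.009G022400	0	0
this_study	Days to maturity	Pv09	5.85	5.85		0	0
pub_26	Seed yield	Pv09	10.00	10.00	Phvul.009G051600	0	1
this_study	Plant height (cm)	Pv09	27.98	27.98	Phvul.009G185100	0	0
this_study	Growth habit	Pv09	30.93	30.93	Phvul.009G204100	1	0
pub_69	Biomass (kg)	Pv10	0.60	0.60	Phvul.010G003600	0	1
pub_47	Seed weight	Pv10	2.60	2.60	Phvul.010G017600	0	1
pub_53	Root rot damage	Pv10	16.40	16.40		0	1
pub_53	Root rot damage	Pv10	19.51	19.51		0	1
pub_53	Root rot damage	Pv10	25.44	25.44		0	1
pub_53	Root rot damage	Pv10	29.88	29.88		0	1
pub_69	Biomass (kg)	Pv10	36.45	36.45	Phvul.010G099100	0	1
this_study	Halo blight damage score	Pv10	41.52	41.52	Phvul.010G133101	0	0
pub_49	Days to flowering	Pv10	42.50	42.50	Phvul.010G142900	0	1
this_study	Growth habit	Pv10	42.79	42.79	Phvul.010G146500	1	0
pub_69	Biomass (kg)	Pv11	1.59	1.59	Phvul.011G020500	0	1
pub_52	Days to flowering	Pv11	4.02	4.02		0	1
pub_47	Days to maturity	Pv11	4.46	4.46	Phvul.011G050300	0	1
pub_52	Days to flowering	Pv11	10.66	10.66		0	1
companion_2020	Days to maturity	Pv11	14.80	14.80		0	0
pub_53	Root rot damage	Pv11	26.41	26.41		0	1
pub_52	Days to flowering	Pv11	27.27	27.27		0	1
pub_52	Days to flowering	Pv11	36.22	36.22		0	1
pub_53	Root rot damage	Pv11	41.36	41.36		0	1
pub_47	Days to maturity	Pv11	45.09	45.09	Phvul.011G158300	0	1
pub_52	Days to flowering	Pv11	45.29	45.29		0	1
pub_47	Growth habit indeterminate	Pv11	46.75	46.75	Phvul.011G164800	0	1
pub_52	Days to flowering	Pv11	47.30	47.30		0	1
pub_53	Root rot damage	Pv11	50.59	50.59		0	1
this_study	Rust damage score	Pv11	50.67	50.67	Phvul.011G193100	1	0
pub_MC	Rust damage score	Pv11	50.67	50.67	Phvul.011G193100	0	1
pub_69	Biomass (kg)	Pv11	52.55	52.55	Phvul.011G207500	0	1
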