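table	gene	name	donor	acceptor	status	rel_prop_normal	freq_pct_normal	freq_count_normal	ratio_normal	rel_prop_tumor	freq_pct_tumor	freq_count_tumor	ratio_tumor	n_normal	n_tumor
1	BRCA1	BRCA1_circRNA_20-18	20	18	known	10.94	84.21	32	4.73	11.18	92.22	83	2.57	38	90
1	BRCA1	BRCA1_circRNA_7-6	7	6	known	10.83	89.47	34	4.68	7.93	87.78	79	1.82	38	90
1	BRCA1	BRCA1_circRNA_17-15	17	15	known	10.31	92.11	35	4.46	9.49	92.22	83	2.18	38	90
1	BRCA1	BRCA1_circRNA_19-18	19	18	known	7.19	78.95	30	3.11	5.80	84.44	76	1.33	38	90
1	BRCA1	BRCA1_circRNA_3-2	3	2	known	5.42	44.74	17	2.34	2.17	46.67	42	0.50	38	90
1	BRCA1	BRCA1_circRNA_10-2	10	2	known	5.00	68.42	26	2.16	3.78	72.22	65	0.87	38	90
1	BRCA1	BRCA1_circRNA_22-20	22	20	known	3.65	50	19	1.58	4.81	87.78	79	1.11	38	90
1	BRCA1	BRCA1_circRNA_10-6	10	6	known	3.33	44.74	17	1.44	2.66	63.33	57	0.61	38	90
1	BRCA1	BRCA1_circRNA_12-11	12	11	known	3.33	55.26	21	1.44	5.25	84.44	76	1.21	38	90
1	BRCA1	BRCA1_circRNA_23-18	23	18	known	3.33	55.26	21	1.44	5.15	81.11	73	1.18	38	90
1	BRCA1	BRCA1_circRNA_19-15	19	15	known	3.23	52.63	20	1.40	2.59	72.22	65	0.60	38	90
1	BRCA1	BRCA1_circRNA_8-6	8	6	known	2.81	55.26	21	1.22	2.08	56.67	51	0.48	38	90
1	BRCA1	BRCA1_circRNA_23-20	23	20	known	2.71	42.11	16	1.17	5.51	81.11	73	1.27	38	90
1	BRCA1	BRCA1_circRNA_21-18	21	18	known	2.40	34.21	13	1.04	2.68	63.33	57	0.62	38	90
1	BRCA1	BRCA1_circRNA_8-3	8	3	known	2.08	42.11	16	0.90	2.91	76.67	69	0.67	38	90
1	BRCA1	BRCA1_circRNA_5q-3	5q	3	novel	1.67	13.16	5	0.72	0.71	22.22	20	0.16	38	90
1	BRCA1	BRCA1_circRNA_22-18	22	18	known	1.56	31.58	12	0.68	2.37	61.11	55	0.54	38	90
1	BRCA1	BRCA1_circRNA_23-15	23	15	known	1.46	28.95	11	0.63	1.24	43.33	39	0.28	38	90
1	BRCA1	BRCA1_circRNA_7-5	7	5	known	1.35	28.95	11	0.59	1.69	41.11	37	0.39	38	90
1	BRCA1	BRCA1_circRNA_20-15	20	15	known	1.15	18.42	7	0.50	1.75	55.56	50	0.40	38	90
1	BRCA1	BRCA1_circRNA_22-15	22	15	known	1.04	26.32	10	0.45	1.69	57.78	52	0.39	38	90
2	BRCA2	BRCA2_circRNA_7-3	7	3	known	22.34	50	19	2.76	26.13	76.67	69	1.48	38	90
2	BRCA2	BRCA2_circRNA_7-4	7	4	known	19.68	55.26	21	2.43	21.18	76.67	69	1.20	38	90
2	BRCA2	BRCA2_circRNA_18-17	18	17	known	12.23	44.74	17	1.51	12.61	61.11	55	0.71	38	90
2	BRCA2	BRCA2_circRNA_7-5	7	5	novel	6.91	21.05	8	0.85	5.97	48.89	44	0.34	38	90
2	BRCA2	BRCA2_circRNA_9-9	9	9	novel	4.79	21.05	8	0.59	2.10	24.44	22	0.12	38	90
2	BRCA2	BRCA2_circRNA_26-13	26	13	novel	4.26	21.05	8	0.53	0.67	8.89	8	0.04	38	90
2	BRCA2	BRCA2_circRNA_21-20	21	20	known	3.72	7.89	3	0.46	1.51	18.89	17	0.09	38	90
2	BRCA2	BRCA2_circRNA_13-11	13	11	known	3.19	13.16	5	0.39	7.39	47.78	43	0.42	38	90
2	BRCA2	BRCA2_circRNA_4-3	4	3	known	3.19	13.16	5	0.39	3.61	32.22	29	0.20	38	90
2	BRCA2	BRCA2_circRNA_14-13	14	13	known	2.66	13.16	5	0.33	1.43	14.44	13	0.08	38	90
2	BRCA2	BRCA2_circRNA_10-4	10	4	known	2.13	7.89	3	0.26	1.01	10	9	0.06	38	90
2	BRCA2	BRCA2_circRNA_13-12	13	12	novel	2.13	5.26	2	0.26	0.76	10	9	0.04	38	90
2	BRCA2	BRCA2_circRNA_6q-2	6q	2	novel	2.13	10.53	4	0.26	0.76	10	9	0.04	38	90
2	BRCA2	BRCA2_circRNA_10-5	10	5	known	1.60	7.89	3	0.20	0.67	7.78	7	0.04	38	90
2	BRCA2	BRCA2_circRNA_10-8	10	8	known	1.60	7.89	3	0.20	1.43	17.78	16	0.08	38	90
2	BRCA2	BRCA2_circRNA_11-11	11	11	known	1.60	7.89	3	0.20	1.18	13.33	12	0.07	38	90
2	BRCA2	BRCA2_circRNA_10-3	10	3	known	1.06	5.26	2	0.13	1.01	12.22	11	0.06	38	90
2	BRCA2	BRCA2_circRNA_19-17	19	17	known	1.06	5.26	2	0.13	3.28	32.22	29	0.19	38	90
2	BRCA2	BRCA2_circRNA_24-19	24	19	known	1.06	5.26	2	0.13	2.10	20	18	0.12	38	90
2	BRCA2	BRCA2_circRNA_24-22	24	22	known	1.06	5.26	2	0.13	1.76	16.67	15	0.10	38	90
2	BRCA2	BRCA2_circRNA_24-21	24	21	known	0.53	2.63	1	0.07	2.44	28.89	26	0.14	38	90
3	BRCA1	BRCA1_circRNA_5q-3	5q	3	novel	1.67	13.16	5	0.72	0.71	22.22	20	0.16	38	90
3	BRCA1	BRCA1_circRNA_23-8p	23	8p	novel	1.15	23.68	9	0.50	0.76	40	36	0.18	38	90
3	BRCA1	BRCA1_circRNA_19-17	19	17	novel	1.04	21.05	8	0.45	0.85	38.89	35	0.19	38	90
3	BRCA1	BRCA1_circRNA_18-2	18	2	novel	0.63	13.16	5	0.27	0.25	14.44	13	0.06	38	90
3	BRCA1	BRCA1_circRNA_16-3	16	3	novel	0.52	13.16	5	0.23	0.07	4.44	4	0.02	38	90
3	BRCA1	BRCA1_circRNA_23-22	23	22	novel	0.42	10.53	4	0.18	0.10	6.67	6	0.02	38	90
3	BRCA1	BRCA1_circRNA_10-8	10	8	novel	0.31	7.89	3	0.14	0.66	27.78	25	0.15	38	90
3	BRCA1	BRCA1_circRNA_20-20	20	20	novel	0.31	5.26	2	0.14	0.41	11.11	10	0.09	38	90
3	BRCA1	BRCA1_circRNA_12-6	12	6	novel	0.10	2.63	1	0.05	0.19	12.22	11	0.04	38	90
3	BRCA1	BRCA1_circRNA_21-20	21	20	novel	0.10	2.63	1	0.05	0.10	6.67	6	0.02	38	90
4	BRCA2	BRCA2_circRNA_7-5	7	5	novel	6.91	21.05	8	0.85	5.97	48.89	44	0.34	38	90
4	BRCA2	BRCA2_circRNA_9-9	9	9	novel	4.79	21.05	8	0.59	2.10	24.44	22	0.12	38	90
4	BRCA2	BRCA2_circRNA_26-13	26	13	novel	4.26	21.05	8	0.53	0.67	8.89	8	0.04	38	90
4	BRCA2	BRCA2_circRNA_13-12	13	12	novel	2.13	5.26	2	0.26	0.76	10	9	0.04	38	90
4	BRCA2	BRCA2_circRNA_6q-2	6q	2	novel	2.13	10.53	4	0.26	0.76	10	9	0.04	38	90
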