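gene	donor	acceptor	name	status	note
BRCA1	10	2	BRCA1_circRNA_10-2	known	
BRCA1	10	6	BRCA1_circRNA_10-6	known	
BRCA1	10	8	BRCA1_circRNA_10-8	novel	
BRCA1	12	11	BRCA1_circRNA_12-11	known	
BRCA1	12	6	BRCA1_circRNA_12-6	novel	
BRCA1	16	3	BRCA1_circRNA_16-3	novel	
BRCA1	17	15	BRCA1_circRNA_17-15	known	
BRCA1	18	2	BRCA1_circRNA_18-2	novel	
BRCA1	19	15	BRCA1_circRNA_19-15	known	
BRCA1	19	17	BRCA1_circRNA_19-17	novel	
BRCA1	19	18	BRCA1_circRNA_19-18	known	
BRCA1	20	15	BRCA1_circRNA_20-15	known	
BRCA1	20	18	BRCA1_circRNA_20-18	known	
BRCA1	20	20	BRCA1_circRNA_20-20	novel	
BRCA1	21	18	BRCA1_circRNA_21-18	known	
BRCA1	21	20	BRCA1_circRNA_21-20	novel	
BRCA1	22	15	BRCA1_circRNA_22-15	known	
BRCA1	22	18	BRCA1_circRNA_22-18	known	
BRCA1	22	20	BRCA1_circRNA_22-20	known	
BRCA1	23	15	BRCA1_circRNA_23-15	known	
BRCA1	23	18	BRCA1_circRNA_23-18	known	
BRCA1	23	20	BRCA1_circRNA_23-20	known	
BRCA1	23	22	BRCA1_circRNA_23-22	novel	
BRCA1	23	8p	BRCA1_circRNA_23-8p	novel	
BRCA1	3	2	BRCA1_circRNA_3-2	known	
BRCA1	5q	3	BRCA1_circRNA_5q-3	novel	
BRCA1	7	5	BRCA1_circRNA_7-5	known	
BRCA1	7	6	BRCA1_circRNA_7-6	known	
BRCA1	8	3	BRCA1_circRNA_8-3	known	
BRCA1	8	6	BRCA1_circRNA_8-6	known	
BRCA2	10	3	BRCA2_circRNA_10-3	known	
BRCA2	10	4	BRCA2_circRNA_10-4	known	
BRCA2	10	5	BRCA2_circRNA_10-5	known	
BRCA2	10	8	BRCA2_circRNA_10-8	known	
BRCA2	11	11	BRCA2_circRNA_11-11	known	
BRCA2	13	11	BRCA2_circRNA_13-11	known	
BRCA2	13	12	BRCA2_circRNA_13-12	novel	
BRCA2	14	13	BRCA2_circRNA_14-13	known	
BRCA2	18	17	BRCA2_circRNA_18-17	known	
BRCA2	19	17	BRCA2_circRNA_19-17	known	
BRCA2	21	20	BRCA2_circRNA_21-20	known	
BRCA2	24	19	BRCA2_circRNA_24-19	known	
BRCA2	24	21	BRCA2_circRNA_24-21	known	
BRCA2	24	22	BRCA2_circRNA_24-22	known	
BRCA2	26	13	BRCA2_circRNA_26-13	novel	
BRCA2	4	3	BRCA2_circRNA_4-3	known	
BRCA2	6q	2	BRCA2_circRNA_6q-2	novel	
BRCA2	7	3	BRCA2_circRNA_7-3	known	
BRCA2	7	4	BRCA2_circRNA_7-4	known	
BRCA2	7	5	BRCA2_circRNA_7-5	novel	
BRCA2	9	9	BRCA2_circRNA_9-9	novel	
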