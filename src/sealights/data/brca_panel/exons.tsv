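gene	label	ordinal	in_canonical
BRCA1	1	1.0	True
BRCA1	2	2.0	True
BRCA1	3	3.0	True
BRCA1	4	4.0	True
BRCA1	5	5.0	True
BRCA1	6	6.0	True
BRCA1	7	7.0	True
BRCA1	8	8.0	True
BRCA1	9	9.0	True
BRCA1	10	10.0	True
BRCA1	11	11.0	True
BRCA1	12	12.0	True
BRCA1	13	13.0	True
BRCA1	14	14.0	True
BRCA1	15	15.0	True
BRCA1	16	16.0	True
BRCA1	17	17.0	True
BRCA1	18	18.0	True
BRCA1	19	19.0	True
BRCA1	20	20.0	True
BRCA1	21	21.0	True
BRCA1	22	22.0	True
BRCA1	23	23.0	True
BRCA1	24	24.0	True
BRCA1	5q	5.5	False
BRCA1	8p	7.5	False
BRCA1	11q	11.5	False
BRCA1	13p	12.5	False
BRCA1	14q	14.5	False
BRCA2	1	1.0	True
BRCA2	2	2.0	True
BRCA2	3	3.0	True
BRCA2	4	4.0	True
BRCA2	5	5.0	True
BRCA2	6	6.0	True
BRCA2	7	7.0	True
BRCA2	8	8.0	True
BRCA2	9	9.0	True
BRCA2	10	10.0	True
BRCA2	11	11.0	True
BRCA2	12	12.0	True
BRCA2	13	13.0	True
BRCA2	14	14.0	True
BRCA2	15	15.0	True
BRCA2	16	16.0	True
BRCA2	17	17.0	True
BRCA2	18	18.0	True
BRCA2	19	19.0	True
BRCA2	20	20.0	True
BRCA2	21	21.0	True
BRCA2	22	22.0	True
BRCA2	23	23.0	True
BRCA2	24	24.0	True
BRCA2	25	25.0	True
BRCA2	26	26.0	True
BRCA2	27	27.0	True
BRCA2	6q	6.5	False
BRCA2	12p	11.5	False
BRCA2	18p	17.5	False
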