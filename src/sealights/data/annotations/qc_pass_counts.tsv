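cohort	tissue	passed	total	printed_pct
validation	breast_tumor	20	23	86
validation	breast_normal_adjacent	6	23	26
validation	prophylactic_mastectomy	12	32	37.5
validation	serous_carcinoma	3	3	100
validation	ovarian_normal	33	41	80.5
validation	salpingian_normal	34	42	81
research	breast_tumor	90	95	94.7
research	breast_normal_adjacent	38	95	40
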