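protein_id	unt_bio_1	unt_bio_2	unt_bio_3	unt_ctrl_1	unt_ctrl_2	unt_ctrl_3	str_bio_1	str_bio_2	str_bio_3	str_ctrl_1	str_ctrl_2	str_ctrl_3	unt_bio_1.peptides	unt_bio_2.peptides	unt_bio_3.peptides	unt_ctrl_1.peptides	unt_ctrl_2.peptides	unt_ctrl_3.peptides	str_bio_1.peptides	str_bio_2.peptides	str_bio_3.peptides	str_ctrl_1.peptides	str_ctrl_2.peptides	str_ctrl_3.peptides
PASS1	100	120	110	10	10	10	200	180	220	10	10	10	3	3	3	0	0	0	4	3	3	0	0	0
PASS2	30	30	30	10	10	10	90	90	90	30	30	30	2	2	2	0	0	0	2	2	2	0	0	0
PASS3	0	50	60	0	0	0	40	0	80	5	5	5	0	2	1	0	0	0	2	0	3	0	0	0
F_PEP	100	100	100	0	0	0	100	100	100	0	0	0	1	1	1	0	0	0	1	1	1	0	0	0
F_CTRL_U	20	20	20	10	10	10	100	100	100	10	10	10	3	3	3	0	0	0	3	3	3	0	0	0
F_CTRL_S	100	100	100	10	10	10	50	50	50	20	20	20	3	3	3	0	0	0	3	3	3	0	0	0
F_PRES1	0	0	90	0	0	0	80	0	0	0	0	0	0	0	4	0	0	0	4	0	0	0	0	0
F_PRES2	5	0	0	0	0	0	0	6	0	0	0	0	2	0	0	0	0	0	2	0	0	0	0	0
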