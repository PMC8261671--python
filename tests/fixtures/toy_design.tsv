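sample_id	condition	assay	replicate	method
unt_bio_1	untreated	biological	1	TOP3
unt_bio_2	untreated	biological	2	TOP3
unt_bio_3	untreated	biological	3	TOP3
unt_ctrl_1	untreated	competition_control	1	TOP3
unt_ctrl_2	untreated	competition_control	2	TOP3
unt_ctrl_3	untreated	competition_control	3	TOP3
str_bio_1	stress	biological	1	TOP3
str_bio_2	stress	biological	2	TOP3
str_bio_3	stress	biological	3	TOP3
str_ctrl_1	stress	competition_control	1	TOP3
str_ctrl_2	stress	competition_control	2	TOP3
str_ctrl_3	stress	competition_control	3	TOP3
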