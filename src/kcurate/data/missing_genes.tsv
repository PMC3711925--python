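symbol	category
KCNMB3P	human_pseudogene
KCTD9P1	human_pseudogene
KCTD9P2	human_pseudogene
KCNE1L	missing_in_finch
KCNE2	missing_in_finch
KCNE5	missing_in_finch
KCNH2	missing_in_finch
KCNIP3	missing_in_finch
KCNK3	missing_in_finch
KCNK4	missing_in_finch
KCNMB3	missing_in_finch
KCNA7	missing_in_birds
KCNAB3	missing_in_birds
KCNC3	missing_in_birds
KCND1	missing_in_birds
KCNH3	missing_in_birds
KCNJ14	missing_in_birds
KCNK6	missing_in_birds
KCTD13	missing_in_birds
KCNN4	missing_in_sauropsids
KCNU1	missing_in_sauropsids
KCNK7	missing_in_tetrapods_or_mammal_specific
KCTD11	missing_in_tetrapods_or_mammal_specific
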