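accession	description	groups_discovered_in	unique_peptides	fold_change	p_value	trend	homologous_protein
Q5FW60	Major urinary protein 20 (Mup20)	both_groups	9	6.25	0.01051	Down	No
B0V388	Novel member of the major urinary protein (Mup) gene family	both_groups	5	5.88	0.02104	Down	No
A2ARV4	Low-density lipoprotein receptor-related protein 2 (Lrp2)	both_groups	77	2.73	0.04849	Up	Yes
P28843	Dipeptidyl peptidase 4 (Dpp4)	both_groups	17	2.97	0.03824	Up	Yes
Q03265	ATP synthase subunit alpha, mitochondrial (Atp5a1)	tumor_only	3				Yes
G3XA48	Isopentenyl-diphosphate Delta-isomerase 1 (Idi1)	tumor_only	3				Yes
G3UYJ7	Predicted gene 20441 (Gm20441)	tumor_only	3				No
P52787	Gastric intrinsic factor (Gif)	control_only	5				Yes
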