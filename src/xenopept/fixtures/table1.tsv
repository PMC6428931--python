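accession	description	psm_count	n_detected	n_group	unique_peptide_count	concentration_pg_ml	walker256_flag	c6_flag
B4DV14	highly similar to Napsin-A	69	4	4	1		0	0
A1A508	PRSS3 protein (PRSS3)	44	1	4	1		0	0
D9YZU5	Beta-globin (HBB)	33	1	4	6	73156.39	0	0
P99999	Cytochrome c (CYCS)	26	3	4	4	235.11	1	1
A8K7G6	highly similar to Homo sapiens Regenerating islet-derived 1 alpha	22	1	4	3		0	0
A0A087WXI5	Cadherin-1 (CDH1)	17	3	4	4	61234.54	1	1
P48304	Lithostathine-1-beta (REG1B)	14	1	4	1		0	1
A0A0A6YYJ4	Trefoil factor 3 (TFF3)	13	2	4	4	13032.49	0	1
P04083	Annexin A1 (ANXA1)	12	1	4	1	25421.29	1	1
P01037	Cystatin-SN (CST1)	11	1	4	5	3490.18	0	0
A0A024RAM2	Glutaredoxin (Thioltransferase) (GLRX)	9	2	4	1		1	0
P01036	Cystatin-S (CST4)	7	1	4	1	4655.98	0	0
A0A1K0GXZ1	Globin C1 (GLNC1)	7	1	4	2		0	0
S6B294	IgG L chain	7	1	4	1		0	0
H9ZYJ2	Thioredoxin (TXN)	7	2	4	2		1	1
P36957	Dihydrolipoyllysine (DLST)	6	1	4	1	4061.93	1	1
V9HWA9	Epididymis secretory sperm binding protein Li 62p (HEL-S-62p)	6	1	4	2		0	0
Q8TAX7	Mucin-7 (MUC7)	6	1	4	3		0	0
Q6N092	DKFZp686K1819	6	2	4	3		0	0
Q99988	Growth/differentiation factor 15 (GDF15)	4	2	4	2	3499.81	1	1
A0A1U9X8X6	CDSN	3	1	4	1		0	0
P04406	Glyceraldehyde-3-phosphate dehydrogenase (GAPDH)	3	1	4	1	20395.34	1	1
P31151	Protein S100-A7 (S100A7)	3	2	4	2	1600.63	0	0
Q96DA0	Zymogen granule protein 16 homolog B (ZG16B)	3	1	4	2	14970.59	0	0
Q8N4F0	BPI fold-containing family B member 2 (BPIFB2)	2	1	4	2	752.72	0	0
A9UFC0	Caspase 14 (CASP14)	2	1	4	2		0	0
Q76LA1	CSTB	2	1	4	2		1	1
P01040	Cystatin-A (CSTA)	2	1	4	2	1309.68	0	0
Q05DB4	HEBP2	2	1	4	2		0	0
A7Y9J9	Mucin 5 AC	2	1	4	2		0	0
Q03403	Trefoil factor 2 (TFF2)	2	1	4	1	59910.81	0	1
Q13867	Bleomycin hydrolase (BLMH)	1	1	4	1	262.38	0	1
Q8TCX0	Delta 2-isopentenyl pyrophosphate transferase-like protein	1	1	4	1		0	0
V9HW80	Epididymis luminal protein 220 (HEL-S-70)	1	1	4	1		0	0
B7Z3K9	Fructose-bisphosphate aldolase	1	1	4	1		1	1
Q6FH62	HSD17B3	1	1	4	1		0	0
X6R7Y7	Intraflagellar transport protein 25 homolog (HSPB11)	1	1	4	1		0	0
Q96P63-2	Serpin B12 (SERPINB12)	1	1	4	1		0	0
P59665	Neutrophil defensin 1 (DEFA1)	1	1	4	1	20375.74	0	0
P01833	Polymeric immunoglobulin receptor (PIGR)	1	1	4	1	129844.97	1	1
A0A158RFU6	RAB7	1	1	4	1		0	1
P29508	Serpin B3 (SERPINB3)	1	1	4	1	26103.15	0	0
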