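Annotation	Gene Name	Fold Change	P-Value
CG4500	heimdall	179.53	8.32E-257
Hsp70Bb	Heat-shock-protein-70Bb	45.15	0
CG30059	-	34.17	4.03E-32
CR44994	-	33.82	2.66E-08
Mal-A8	Maltase A8	30.60	5.81E-12
CG34040	-	22.44	6.27E-06
Mal-A7	Maltase A7	20.80	4.81E-12
Cyp6d2	Cyp6d2	15.82	7.14E-45
lectin-24A	lectin-24A	15.52	3.16E-07
squ	squash	11.89	8.54E-22
Amy-p	Amylase proximal	8.71	7.56E-09
alc	alicorn	-2.50	0
Obp56a	Odorant-binding protein 56a	-6.55	5.90E-161
CG32437	-	-6.90	4.60E-07
CG8563	-	-6.94	7.89E-15
Obp99d	Odorant-binding protein 99d	-14.39	2.68E-36
CG43291	-	-18.69	9.75E-24
CG12971	-	-35.38	1.26E-30
CG17242	-	-40.90	2.58E-05
CR45600	-	-62.45	0
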