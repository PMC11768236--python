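pt	n_serious	n_nonserious	statistic	test
Malaise	246	425	204.663	pearson
Condition aggravated	361	277	11.561	pearson
Arthralgia	264	231	20.233	pearson
Rash	228	216	26.297	pearson
Pneumonia	330	3	186.728	yates
Cough	177	119	1.324	pearson
COVID-19	99	158	66.720	pearson
Abdominal pain	193	49	29.356	pearson
Illness	72	170	115.819	pearson
Nasopharyngitis	113	118	19.840	pearson
Influenza	81	106	31.321	pearson
Infection	127	36	15.626	pearson
Oropharyngeal pain	79	59	1.976	pearson
Rhinorrhea	61	62	9.539	pearson
Inflammation	87	23	12.253	pearson
C-reactive protein increased	99	10	36.325	pearson
Cellulitis	91	2	47.105	yates
Nasal congestion	41	44	7.983	pearson
Lymphadenopathy	59	18	6.140	pearson
Upper respiratory tract infection	39	38	5.060	pearson
Viral infection	52	15	6.145	pearson
Ear infection	30	36	8.746	pearson
Gastroenteritis	53	4	20.746	yates
Disease recurrence	43	14	3.786	pearson
Serum ferritin increased	45	6	13.950	pearson
Pharyngitis streptococcal	14	36	26.338	pearson
Concomitant disease aggravated	47	1	23.660	yates
Body temperature increased	20	25	6.664	pearson
SARS-CoV-2 test positive	10	33	29.199	pearson
Eosinophilia and systemic symptoms	40	0	NA	fisher
Tonsillitis	34	4	10.325	yates
Deafness	35	1	16.663	yates
Pharyngitis	23	12	0.110	pearson
Transaminases increased	31	3	10.409	yates
Inflammatory marker increased	24	7	2.765	pearson
Mouth ulceration	23	7	2.403	pearson
Blood lactate dehydrogenase increased	28	2	10.582	yates
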