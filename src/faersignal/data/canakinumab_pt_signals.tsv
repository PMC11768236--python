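soc	pt	cases	ror	ror_lo	ror_hi	ic	ic025	deaths	listing	evidence	published_band	published_score
Blood and lymphatic system disorders	Lymphadenopathy	77	4.88	3.90	6.11	2.28	1.82	7	NA	++	moderate	5
Blood and lymphatic system disorders	Splenomegaly	24	4.55	3.05	6.80	2.18	1.46	4	NA	+	weak	3
Blood and lymphatic system disorders	Lymphadenitis	10	9.51	5.11	17.70	3.24	1.74	0	NA	+	weak	4
Cardiac disorders	Pericarditis	28	4.55	3.14	6.59	2.18	1.50	0	IME	+	weak	4
Ear and labyrinth disorders	Deafness	36	3.02	2.18	4.19	1.59	1.15	0	DME	-	weak	4
Ear and labyrinth disorders	Ear pain	26	2.89	1.97	4.25	1.53	1.04	0	NA	-	weak	2
Gastrointestinal disorders	Abdominal pain	242	2.31	2.04	2.62	1.20	1.06	11	NA	++	moderate	5
Gastrointestinal disorders	Gastroenteritis	57	8.95	6.90	11.61	3.15	2.43	0	NA	++	moderate	6
Gastrointestinal disorders	Mouth ulceration	30	3.23	2.26	4.62	1.69	1.18	2	NA	+	weak	3
Gastrointestinal disorders	Gastroenteritis viral	29	3.45	2.40	4.97	1.78	1.24	0	NA	+	weak	3
General disorders and administration site conditions	Malaise	671	3.18	2.95	3.44	1.65	1.52	11	NA	+	weak	4
General disorders and administration site conditions	Condition aggravated	638	4.98	4.60	5.39	2.29	2.11	12	NA	+	weak	4
General disorders and administration site conditions	Illness	242	6.07	5.35	6.89	2.59	2.28	3	NA	+	moderate	5
General disorders and administration site conditions	Inflammation	110	4.86	4.03	5.87	2.27	1.89	3	NA	++	moderate	5
General disorders and administration site conditions	Disease recurrence	57	2.52	1.94	3.26	1.33	1.02	2	NA	+	weak	4
General disorders and administration site conditions	Concomitant disease aggravated	48	15.44	11.62	20.52	3.93	2.96	4	NA	+	weak	4
General disorders and administration site conditions	Symptom recurrence	21	8.32	5.42	12.78	3.05	1.99	0	NA	+	weak	4
General disorders and administration site conditions	Concomitant disease progression	17	19.64	12.18	31.69	4.28	2.65	3	NA	+	weak	4
Hepatobiliary disorders	Hepatomegaly	28	6.87	4.74	9.96	2.77	1.91	5	NA	+	weak	4
Immune system disorders	Decreased immune responsiveness	22	4.77	3.14	7.26	2.25	1.48	3	NA	+	weak	3
Immune system disorders	Immunosuppression	13	3.43	1.99	5.92	1.78	1.03	0	IME	++	moderate	5
Infections and infestations	Infection	163	2.47	2.12	2.89	1.30	1.11	12	NA	++	moderate	5
Infections and infestations	Viral infection	67	4.55	3.58	5.79	2.18	1.72	4	NA	++	moderate	5
Infections and infestations	Ear infection	66	5.37	4.21	6.84	2.42	1.90	0	NA	-	weak	4
Infections and infestations	Conjunctivitis	28	3.45	2.38	4.99	1.78	1.23	0	NA	++	weak	4
Infections and infestations	Abscess	26	3.56	2.43	5.24	1.83	1.25	0	NA	++	weak	4
Infections and infestations	Appendicitis	23	5.60	3.72	8.43	2.48	1.65	0	IME	-	weak	4
Infections and infestations	Streptococcal infection	22	9.48	6.23	14.42	3.24	2.13	2	NA	+	weak	4
Infections and infestations	Otitis media	19	12.97	8.26	20.37	3.69	2.35	1	NA	++	moderate	5
Infections and infestations	Epstein-Barr virus infection	18	6.70	4.21	10.64	2.74	1.72	1	NA	-	weak	3
Infections and infestations	Meningitis	17	5.86	3.64	9.43	2.55	1.58	0	IME	+	moderate	5
Infections and infestations	Coronavirus infection	15	4.41	2.65	7.31	2.14	1.29	2	NA	++	weak	4
Infections and infestations	Infectious mononucleosis	11	11.00	6.08	19.89	3.45	1.91	0	NA	-	weak	3
Infections and infestations	Rhinovirus infection	10	6.27	3.37	11.66	2.64	1.42	1	NA	-	weak	3
Injury, poisoning, and procedural complications	Drug reaction with eosinophilia and systemic symptoms	40	3.28	2.40	4.47	1.71	1.25	4	DME	-	weak	4
Injury, poisoning, and procedural complications	Brain oedema	16	3.02	1.85	4.94	1.59	0.98	9	IME	-	moderate	5
Investigations	C-reactive protein increased	109	7.10	5.88	8.57	2.82	2.33	9	NA	++	moderate	6
Investigations	Serum ferritin increased	51	22.06	16.73	29.08	4.44	3.37	5	NA	+	moderate	5
Investigations	Body temperature increased	45	5.07	3.78	6.79	2.34	1.74	0	NA	++	moderate	5
Investigations	SARS-CoV-2 test positive	43	6.10	4.52	8.24	2.60	1.93	0	NA	+	weak	4
Investigations	Transaminases increased	34	3.40	2.43	4.76	1.76	1.26	1	NA	++	weak	4
Investigations	Inflammatory marker increased	31	13.51	9.48	19.23	3.74	2.63	0	NA	+	weak	4
Investigations	Blood lactate dehydrogenase increased	30	4.88	3.41	6.98	2.28	1.59	4	NA	-	weak	2
Investigations	Lymphocyte count decreased	29	3.37	2.34	4.86	1.75	1.22	1	NA	++	weak	4
Investigations	Red blood cell sedimentation rate increased	27	5.99	4.10	8.73	2.58	1.77	2	NA	+	weak	4
Investigations	Body temperature decreased	18	3.95	2.49	6.27	1.98	1.25	0	NA	++	weak	4
Investigations	Blood fibrinogen decreased	9	20.37	10.56	39.31	4.33	2.25	2	NA	-	weak	2
Musculoskeletal and connective tissue disorders	Arthralgia	495	2.61	2.38	2.85	1.37	1.25	6	NA	++	moderate	5
Nervous system disorders	Intracranial pressure increased	12	4.87	2.76	8.58	2.28	1.29	0	IME	-	weak	3
Psychiatric disorders	Cushingoid	11	7.87	4.35	14.23	2.97	1.64	0	NA	-	weak	3
Respiratory, thoracic, and mediastinal disorders	Pneumonia	333	2.25	2.02	2.51	1.16	1.04	45	IME	++	moderate	6
Respiratory, thoracic, and mediastinal disorders	Cough	296	2.29	2.04	2.56	1.18	1.06	9	NA	++	moderate	5
Respiratory, thoracic, and mediastinal disorders	COVID-19	257	2.88	2.55	3.26	1.52	1.34	24	NA	-	weak	3
Respiratory, thoracic, and mediastinal disorders	Nasopharyngitis	231	2.66	2.33	3.02	1.40	1.23	5	NA	++	moderate	5
Respiratory, thoracic, and mediastinal disorders	Influenza	187	3.67	3.17	4.23	1.87	1.62	0	NA	++	moderate	5
Respiratory, thoracic, and mediastinal disorders	Oropharyngeal pain	138	3.02	2.55	3.57	1.59	1.34	3	NA	++	moderate	5
Respiratory, thoracic, and mediastinal disorders	Rhinorrhea	123	4.08	3.42	4.87	2.02	1.69	1	NA	+	weak	4
Respiratory, thoracic, and mediastinal disorders	Nasal congestion	85	3.17	2.56	3.92	1.66	1.34	0	NA	+	weak	4
Respiratory, thoracic, and mediastinal disorders	Upper respiratory tract infection	77	3.59	2.87	4.50	1.84	1.47	0	NA	++	moderate	5
Respiratory, thoracic, and mediastinal disorders	Pharyngitis streptococcal	50	9.76	7.39	12.89	3.28	2.48	2	NA	++	moderate	5
Respiratory, thoracic, and mediastinal disorders	Tonsillitis	38	15.60	11.33	21.47	3.95	2.87	0	NA	++	moderate	5
Respiratory, thoracic, and mediastinal disorders	Pharyngitis	35	6.13	4.39	8.54	2.61	1.87	0	NA	++	moderate	5
Respiratory, thoracic, and mediastinal disorders	Rhinitis	17	4.70	2.92	7.57	2.23	1.38	0	NA	++	weak	4
Respiratory, thoracic, and mediastinal disorders	Pleurisy	16	5.93	3.63	9.69	2.56	1.57	1	NA	-	weak	3
Skin and subcutaneous tissue disorders	Rash	444	2.29	2.08	2.51	1.18	1.07	5	NA	++	moderate	5
Skin and subcutaneous tissue disorders	Cellulitis	93	3.93	3.20	4.82	1.97	1.61	3	NA	-	weak	3
Skin and subcutaneous tissue disorders	Subcutaneous abscess	18	7.93	4.99	12.60	2.98	1.88	0	NA	-	weak	3
Skin and subcutaneous tissue disorders	Erysipelas	18	7.65	4.82	12.16	2.93	1.84	1	IME	-	weak	4
Skin and subcutaneous tissue disorders	Impetigo	14	21.86	12.90	37.04	4.43	2.62	0	NA	++	moderate	5
Skin and subcutaneous tissue disorders	Varicella	12	11.23	6.36	19.81	3.48	1.97	0	NA	++	moderate	5
Vascular disorders	Papilledema	11	5.74	3.18	10.38	2.52	1.39	0	IME	-	weak	4
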