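index	label	range_start	range_end
0	Intestinal infectious diseases	A00	A09
1	Tuberculosis	A15	A19
2	Certain zoonotic bacterial diseases	A20	A28
3	Other bacterial diseases	A30	A49
4	Infections with a predominantly sexual mode of transmission	A50	A64
5	Other spirochaetal diseases	A65	A69
6	Other diseases caused by chlamydiae	A70	A74
7	Rickettsioses	A75	A79
8	Viral infections of the central nervous system	A80	A89
9	Arthropod-borne viral fevers and viral haemorrhagic fevers	A90	A99
10	Viral infections characterized by skin and mucous membrane lesions	B00	B09
11	Viral hepatitis	B15	B19
12	Human immunodeficiency virus [HIV] disease	B20	B24
13	Other viral diseases	B25	B34
14	Mycoses	B35	B49
15	Protozoal diseases	B50	B64
16	Helminthiases	B65	B83
17	Pediculosis, acariasis and other infestations	B85	B89
18	Sequelae of infectious and parasitic diseases	B90	B94
19	Bacterial, viral and other infectious agents	B95	B98
20	Other infectious diseases	B99	B99
21	Malignant neoplasms	C00	C97
22	In situ neoplasms	D00	D09
23	Benign neoplasms	D10	D36
24	Neoplasms of uncertain or unknown behaviour	D37	D48
25	Nutritional anaemias	D50	D53
26	Haemolytic anaemias	D55	D59
27	Aplastic and other anaemias	D60	D64
28	Coagulation defects, purpura and other haemorrhagic conditions	D65	D69
29	Other diseases of blood and blood-forming organs	D70	D77
30	Certain disorders involving the immune mechanism	D80	D89
31	Disorders of thyroid gland	E00	E07
32	Diabetes mellitus	E10	E14
33	Other disorders of glucose regulation and pancreatic internal secretion	E15	E16
34	Disorders of other endocrine glands	E20	E35
35	Malnutrition	E40	E46
36	Other nutritional deficiencies	E50	E64
37	Obesity and other hyperalimentation	E65	E68
38	Metabolic disorders	E70	E90
39	Organic, including symptomatic, mental disorders	F00	F09
40	Mental and behavioural disorders due to psychoactive substance use	F10	F19
41	Schizophrenia, schizotypal and delusional disorders	F20	F29
42	Mood [affective] disorders	F30	F39
43	Neurotic, stress-related and somatoform disorders	F40	F48
44	Behavioural syndromes associated with physiological disturbances and physical factors	F50	F59
45	Disorders of adult personality and behaviour	F60	F69
46	Mental retardation	F70	F79
47	Disorders of psychological development	F80	F89
48	Behavioural and emotional disorders with onset usually occurring in childhood and adolescence	F90	F98
49	Unspecified mental disorder	F99	F99
50	Inflammatory diseases of the central nervous system	G00	G09
51	Systemic atrophies primarily affecting the central nervous system	G10	G13
52	Extrapyramidal and movement disorders	G20	G26
53	Other degenerative diseases of the nervous system	G30	G32
54	Demyelinating diseases of the central nervous system	G35	G37
55	Episodic and paroxysmal disorders	G40	G47
56	Nerve, nerve root and plexus disorders	G50	G59
57	Polyneuropathies and other disorders of the peripheral nervous system	G60	G64
58	Diseases of myoneural junction and muscle	G70	G73
59	Cerebral palsy and other paralytic syndromes	G80	G83
60	Other disorders of the nervous system	G90	G99
61	Disorders of eyelid, lacrimal system and orbit	H00	H06
62	Disorders of conjunctiva	H10	H13
63	Disorders of sclera, cornea, iris and ciliary body	H15	H22
64	Disorders of lens	H25	H28
65	Disorders of choroid and retina	H30	H36
66	Glaucoma	H40	H42
67	Disorders of vitreous body and globe	H43	H45
68	Disorders of optic nerve and visual pathways	H46	H48
69	Disorders of ocular muscles, binocular movement, accommodation and refraction	H49	H52
70	Visual disturbances and blindness	H53	H54
71	Other disorders of eye and adnexa	H55	H59
72	Diseases of external ear	H60	H62
73	Diseases of middle ear and mastoid	H65	H75
74	Diseases of inner ear	H80	H83
75	Other disorders of ear	H90	H95
76	Acute rheumatic fever	I00	I02
77	Chronic rheumatic heart diseases	I05	I09
78	Hypertensive diseases	I10	I15
79	Ischaemic heart diseases	I20	I25
80	Pulmonary heart disease and diseases of pulmonary circulation	I26	I28
81	Other forms of heart disease	I30	I52
82	Cerebrovascular diseases	I60	I69
83	Diseases of arteries, arterioles and capillaries	I70	I79
84	Diseases of veins, lymphatic vessels and lymph nodes, not elsewhere classified	I80	I89
85	Other and unspecified disorders of the circulatory system	I95	I99
86	Acute upper respiratory infections	J00	J06
87	Influenza and pneumonia	J09	J18
88	Other acute lower respiratory infections	J20	J22
89	Other diseases of upper respiratory tract	J30	J39
90	Chronic lower respiratory diseases	J40	J47
91	Lung diseases due to external agents	J60	J70
92	Other respiratory diseases principally affecting the interstitium	J80	J84
93	Suppurative and necrotic conditions of lower respiratory tract	J85	J86
94	Other diseases of pleura	J90	J94
95	Other diseases of the respiratory system	J95	J99
96	Diseases of oral cavity, salivary glands and jaws	K00	K14
97	Diseases of oesophagus, stomach and duodenum	K20	K31
98	Diseases of appendix	K35	K38
99	Hernia	K40	K46
100	Noninfective enteritis and colitis	K50	K52
101	Other diseases of intestines	K55	K63
102	Diseases of peritoneum	K65	K67
103	Diseases of liver	K70	K77
104	Disorders of gallbladder, biliary tract and pancreas	K80	K87
105	Other diseases of the digestive system	K90	K93
106	Infections of the skin and subcutaneous tissue	L00	L08
107	Bullous disorders	L10	L14
108	Dermatitis and eczema	L20	L30
109	Papulosquamous disorders	L40	L45
110	Urticaria and erythema	L50	L54
111	Radiation-related disorders of the skin and subcutaneous tissue	L55	L59
112	Disorders of skin appendages	L60	L75
113	Other disorders of the skin and subcutaneous tissue	L80	L99
114	Arthropathies	M00	M25
115	Systemic connective tissue disorders	M30	M36
116	Dorsopathies	M40	M54
117	Soft tissue disorders	M60	M79
118	Osteopathies and chondropathies	M80	M94
119	Other disorders of the musculoskeletal system and connective tissue	M95	M99
120	Glomerular diseases	N00	N08
121	Renal tubulo-interstitial diseases	N10	N16
122	Renal failure	N17	N19
123	Urolithiasis	N20	N23
124	Other disorders of kidney and ureter	N25	N29
125	Other diseases of urinary system	N30	N39
126	Diseases of male genital organs	N40	N51
127	Disorders of breast	N60	N64
128	Inflammatory diseases of female pelvic organs	N70	N77
129	Noninflammatory disorders of female genital tract	N80	N98
130	Other disorders of the genitourinary system	N99	N99
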