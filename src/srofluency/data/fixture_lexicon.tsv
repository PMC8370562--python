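word	category	typicality	aoa	concreteness	frequency	prevalence	recognition_time	valence	arousal	dominance	boi	phonemic	syllables
DOG	ANIMALS	6.80	2.90	4.90	5.85	2.40	-0.72	7.00	4.20	5.90	6.40	dɒg	1
CAT	ANIMALS	6.75	2.80	4.92	5.60	2.41	-0.70	6.95	4.00	5.70	6.30	kæt	1
HORSE	ANIMALS	6.10	3.60	4.95	5.10	2.35	-0.62	6.05	4.40	4.90	5.60	hɔs	1
SHEEP	ANIMALS	5.90	3.70	4.93	4.70	2.33	-0.60	5.32	3.30	5.40	4.90	ʃip	1
LAMB	ANIMALS	4.80	4.10	4.80	4.40	2.30	-0.55	6.60	3.40	5.80	5.10	læm	1
APE	ANIMALS	4.20	5.50	4.70	3.90	2.10	-0.40	5.20	4.60	4.30	4.20	eɪp	1
GORILLA	ANIMALS	4.60	5.90	4.88	4.00	2.25	-0.45	5.50	5.20	3.80	3.90	gərɪlə	3
OSTRICH	ANIMALS	1.36	7.80	4.85	3.20	2.05	-0.20	5.40	4.30	4.60	3.50	ɒstrɪʧ	2
MOOSE	ANIMALS	6.42	6.90	4.90	3.40	2.15	-0.30	5.60	4.10	4.20	3.70	mus	1
WASP	ANIMALS	3.10	5.20	4.75	3.80	2.28	-0.42	2.71	5.90	3.60	2.80	wɒsp	1
PANDA	ANIMALS	3.90	5.10	4.89	3.70	2.31	-0.38	7.55	4.00	5.00	3.60	pændə	2
DUCK	ANIMALS	5.70	3.53	4.91	4.60	2.36	-0.58	6.30	3.60	5.60	5.30	dʌk	1
CONDOR	ANIMALS	1.80	13.08	4.60	2.30	1.20	0.05		4.70	4.00	2.90	kɒndɔ	2
THRUSH	ANIMALS	2.40	9.50	3.92	2.60	1.50	0.02	5.70	3.50	4.90	3.10	θrʌʃ	1
WALRUS	ANIMALS	2.90	7.20	5.00	2.90	2.00	-0.15	5.45	3.90	4.40	3.00	wɔlrəs	2
MANATEE	ANIMALS	1.90	10.40	4.70	2.08	0.90	0.12	6.00	3.20	4.50	2.70	mænəti	3
FISH	ANIMALS	5.40	3.10	4.80	5.19	2.42	-0.66	6.42	3.10	5.50	5.70	fɪʃ	1
DORMOUSE	ANIMALS	1.70	9.90	4.65	2.10	0.31	0.15	6.10	3.00	5.20	2.60	dɔmaʊs	2
SLOTH	ANIMALS	2.50	8.60	4.78	2.70	2.58	-0.05	5.90	2.60	5.10	2.50	sləʊθ	1
SPIDER	ANIMALS	3.50	4.30	4.86	4.30	2.39	-0.69	3.30	6.10	3.90	3.20	spaɪdə	2
ANTEATER	ANIMALS	2.00	8.10	4.72	2.40	1.80	0.10	5.55	3.40	4.70	2.80	æntitə	3
SEAL	ANIMALS	3.80	5.40	4.83	3.90	2.32	-0.44	6.20	2.50	5.00	3.40	sil	1
CROCODILE	ANIMALS	4.40	5.00	4.94	3.95	2.34	-0.48	4.10	6.48	3.20	2.90	krɒkədaɪl	3
BEAR	ANIMALS	5.00	4.00	4.87	4.80	2.38	-0.59	5.33	5.50	3.59	3.80	beə	1
BULL	ANIMALS	4.30	4.90	4.84	4.50	2.37	-0.52	4.70	5.70	6.89	4.00	bʊl	1
PLATYPUS	ANIMALS	1.60	9.20	4.68	2.20	1.10	0.08	5.80	3.70	4.80	3.04	plætɪpəs	3
PHEASANT	ANIMALS	2.70	8.00	4.76	2.80	1.90	-0.02	5.50	3.50	5.00	3.30	fɛzənt	2
BUFFALO	ANIMALS	3.20	6.50	4.82	3.30	2.20	-0.25	5.10	4.50	3.70	3.10	bʌfələʊ	3
IGUANA	ANIMALS	2.10	8.90	4.74	2.50	1.70	0.06	5.00	4.40	4.30	2.95	ɪgwɑnə	3
SHRIMP	ANIMALS	2.60	6.20	4.79	3.60	2.26	-0.35	5.30	3.30	5.40	4.10	ʃrɪmp	1
PARROT	ANIMALS	4.10	5.30	4.90	3.85	2.30	-0.41	6.10	4.30	5.10	3.90	pærət	2
HORNET	ANIMALS	2.30	8.40	4.71	2.55	1.60	0.04	3.00	5.80	3.50	2.60	hɔnɪt	2
PANTHER	ANIMALS	3.60	6.80	4.85	3.10	2.18	-0.28	5.20	5.60	3.40	2.75	pænθə	2
OCELOT	ANIMALS	1.50	11.20	4.55	1.90	0.60	0.20	5.60	4.20	4.10	2.55	ɒsəlɒt	3
OTTER	ANIMALS	3.00	6.60	4.88	3.00	2.22	-0.24	6.50	3.60	5.30	3.20	ɒtə	2
OX	ANIMALS	2.80	7.00	4.81	2.95	2.12	-0.18	5.00	3.80	4.60	3.60	ɒks	1
CATERPILLAR	ANIMALS	2.20	4.70	4.77	3.50	2.29	-0.37	5.70	3.20	5.90	4.30	kætəpɪlə	4
GUINEA PIG	ANIMALS	3.40	5.60	4.89	3.40	2.27	-0.33	6.70	3.50	5.80	5.50	gɪnipɪg	3
HIPPOPOTAMUS	ANIMALS	3.30	5.80	4.92	3.20	2.24	-0.31	5.90	4.10	3.90	3.00	hɪpəpɒtəməs	5
MOUSE	ANIMALS	5.20	3.80	4.80	4.90	2.40	-0.63	4.80	4.00	6.00	4.70	maʊs	1
APPLE	FRUITS	6.90	2.70	4.95	5.40	2.43	-0.71	6.62	3.10	6.20	6.50	æpəl	2
KIWI	FRUITS	4.50	6.10	4.90	3.60	2.21	-0.29	6.11	3.30	6.00	5.90	kiwi	2
GRAPE	FRUITS	5.60	4.20	4.93	4.20	2.35	-0.51	6.70	3.00	6.30	6.10	greɪp	1
RAISIN	FRUITS	3.70	4.80	4.85	3.80	2.31	-0.43	5.90	2.80	6.10	5.70	reɪzən	2
BANANA	FRUITS	6.50	2.95	4.96	5.00	2.42	-0.68	6.71	3.00	6.40	6.60	bənɑnə	3
PEAR	FRUITS	5.80	3.90	4.91	4.10	2.36	-0.49	6.70	2.90	6.20	6.20	peə	1
ORANGE	FRUITS	6.30	3.20	4.94	5.20	2.41	-0.65	6.81	3.20	6.30	6.40	ɒrɪnʤ	2
LEMON	FRUITS	5.10	4.40	4.92	4.40	2.38	-0.54	6.37	3.40	6.10	6.00	lɛmən	2
PASSION FRUIT	FRUITS	2.90	8.20	4.80	2.70	1.95	-0.08	6.40	3.80	5.70	5.20	pæʃənfrut	3
RASPBERRY	FRUITS	4.70	4.60	4.89	3.90	2.33	-0.46	7.30	3.30	6.00	5.60	rɑzbəri	3
HAW	FRUITS	1.40	12.50	4.40	1.60	0.40	0.25	4.35	2.90	4.90	3.80	hɔ	1
PEACH	FRUITS	5.30	4.50	4.92	4.00	2.34	-0.47	6.83	3.10	6.20	6.10	piʧ	1
MELON	FRUITS	4.90	4.90	4.90	3.85	2.32	-0.45	6.32	2.90	6.10	5.80	mɛlən	2
PLUM	FRUITS	4.60	5.00	4.88	3.70	2.30	-0.40	6.15	2.90	6.00	5.90	plʌm	1
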