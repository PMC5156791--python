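# Candidate biomarker miRNAs for the two acute coronary syndrome subtypes
# (acute myocardial infarction, AMI; unstable angina, UA), with their
# published network statistics: N (total targets), NOD (uniquely targeted
# genes), TF (transcription-factor targets) and the count of significantly
# enriched pathways each miRNA's unique targets touch.
subtype	mirna	N	NOD	TF	pathways
AMI	miR-155	185	64	39	16
AMI	miR-30e	356	32	56	5
AMI	miR-98	329	24	62	2
AMI	miR-23b	211	18	34	5
AMI	miR-204	198	15	40	10
AMI	miR-34a	80	14	15	5
AMI	let-7g	199	13	34	24
AMI	miR-576-3p	133	13	23	0
AMI	miR-346	31	13	5	5
AMI	miR-454	298	13	43	0
AMI	miR-532-3p	112	12	18	5
AMI	miR-145	55	11	11	8
AMI	miR-340*	256	11	37	3
AMI	miR-126	34	10	5	29
AMI	miR-621	65	10	13	9
AMI	miR-142-3p	87	8	18	3
AMI	miR-31	34	7	8	5
AMI	miR-600	127	7	23	1
AMI	miR-491-3p	119	6	21	0
AMI	miR-603	149	6	32	2
AMI	miR-93	394	6	68	0
AMI	miR-934	72	5	12	0
AMI	miR-27a	50	5	15	3
AMI	miR-548b-3p	103	5	18	0
AMI	miR-101	69	4	18	4
AMI	miR-128	22	4	4	0
AMI	miR-95	69	4	10	0
UA	miR-197	151	32	24	2
UA	miR-125b	109	30	20	4
UA	miR-590-3p	255	18	44	2
UA	miR-22*	158	16	32	0
UA	miR-204	198	15	40	2
UA	miR-34a	80	14	15	6
UA	miR-486-3p	152	13	23	2
UA	let-7g	199	13	34	13
UA	miR-346	31	13	5	4
UA	miR-340	256	11	37	1
UA	miR-340*	256	11	37	1
UA	miR-196b	165	11	27	5
UA	miR-145	55	11	11	3
UA	miR-324-3p	84	10	12	1
UA	miR-126	34	10	5	13
UA	miR-106b	376	9	61	1
UA	miR-885-5p	89	9	14	0
UA	miR-132	46	8	7	0
UA	miR-17	80	8	13	5
UA	miR-597	76	8	12	2
UA	miR-142-3p	87	8	18	1
UA	miR-25	260	7	40	0
UA	miR-590-5p	112	7	23	0
UA	miR-324-5p	78	7	18	2
UA	miR-93	394	6	68	0
UA	miR-618	112	6	17	0
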