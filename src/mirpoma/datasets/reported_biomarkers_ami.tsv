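# Partial literature-derived list of circulating miRNA biomarkers reported
# for acute myocardial infarction (AMI) in human case/control studies.
mirna	subtype	role	direction
miR-155	AMI	prognostic	up
miR-380*	AMI	prognostic	unknown
miR-16	AMI	prognostic	unknown
miR-27a	AMI	prognostic	up
miR-101	AMI	prognostic	mixed
miR-150	AMI	prognostic	unknown
miR-208b	AMI	both	unknown
miR-133a	AMI	both	unknown
miR-34a	AMI	prognostic	unknown
miR-126	AMI	diagnostic	down
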