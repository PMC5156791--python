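# Partial literature-derived list of circulating miRNA biomarkers reported
# for unstable angina (UA) in human case/control studies.
mirna	subtype	role	direction
miR-132	UA	diagnostic	unknown
miR-150	UA	diagnostic	unknown
miR-186	UA	diagnostic	unknown
miR-133a	UA	both	unknown
miR-208b	UA	both	unknown
miR-106b	UA	diagnostic	up
miR-25	UA	diagnostic	up
miR-590-5p	UA	diagnostic	up
miR-21	UA	diagnostic	up
miR-126	UA	diagnostic	unknown
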