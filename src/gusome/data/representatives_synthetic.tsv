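# representative GUS annotations; positions 1-based, intervals closed
id	gus_class	catalytic_positions	loop1_window	loop2_window	fmn_segment	taxonomy
rep_L1_1	L1	50:N;84:E;164:Y;227:E;277:K;332:Y;374:R	117-137	302-305	.	Bacteroides synth-A
rep_L1_2	L1	50:N;84:E;164:Y;227:E;277:K;332:Y;374:R	117-137	302-305	.	Faecalibacterium synth-B
rep_L1_3	L1	50:N;84:E;164:Y;227:E;277:K;332:Y;374:R	117-137	302-305	.	Roseburia synth-C
rep_mL1_1	mL1	50:N;84:E;155:Y;218:E;268:K;323:Y;365:R	117-128	293-296	.	Eubacterium synth-D
rep_mL1_2	mL1	50:N;84:E;155:Y;218:E;268:K;323:Y;365:R	117-128	293-296	.	Clostridium synth-E
rep_L2_1	L2	50:N;84:E;147:Y;210:E;260:K;332:Y;374:R	117-120	285-305	.	Parabacteroides synth-F
rep_L2_2	L2	50:N;84:E;147:Y;210:E;260:K;332:Y;374:R	117-120	285-305	.	Blautia synth-G
rep_L2_3	L2	50:N;84:E;147:Y;210:E;260:K;332:Y;374:R	117-120	285-305	.	Ruminococcus synth-H
rep_mL2_1	mL2	50:N;84:E;147:Y;210:E;260:K;323:Y;365:R	117-120	285-296	.	Bacteroides synth-A
rep_mL2_2	mL2	50:N;84:E;147:Y;210:E;260:K;323:Y;365:R	117-120	285-296	.	Faecalibacterium synth-B
rep_mL1_2_1	mL1_2	50:N;84:E;155:Y;218:E;268:K;331:Y;373:R	117-128	293-304	.	Roseburia synth-C
rep_mL1_2_2	mL1_2	50:N;84:E;155:Y;218:E;268:K;331:Y;373:R	117-128	293-304	.	Eubacterium synth-D
rep_NL_1	NL	50:N;84:E;147:Y;210:E;260:K;315:Y;357:R	117-120	285-288	.	Clostridium synth-E
rep_NL_2	NL	50:N;84:E;147:Y;210:E;260:K;315:Y;357:R	117-120	285-288	.	Parabacteroides synth-F
rep_NL_3	NL	50:N;84:E;147:Y;210:E;260:K;315:Y;357:R	117-120	285-288	.	Blautia synth-G
rep_FMN_1	FMN	50:N;84:E;147:Y;210:E;260:K;315:Y;357:R	117-120	285-288	421-540	Ruminococcus synth-H
rep_FMN_2	FMN	50:N;84:E;147:Y;210:E;260:K;315:Y;357:R	117-120	285-288	421-540	Bacteroides synth-A
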