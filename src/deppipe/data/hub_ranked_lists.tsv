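method	node
degree	HSPA4
degree	ALYREF
degree	ALDH6A1
degree	HNRNPM
degree	RAE1
degree	CARM1
degree	MRPS30
degree	DBT
degree	HNRNPL
degree	PRPF19
degree	MRPL10
degree	RPL23L
degree	VDAC1
degree	ACAA2
degree	PML
degree	EIF3K
degree	RPS23
degree	RPS18
degree	STUB1
degree	GNA11
degree	MLYCD
mcc	ALYREF
mcc	HSPA4
mcc	ALDH6A1
mcc	HNRNPL
mcc	HNRNPM
mcc	RAE1
mcc	CARM1
mcc	MRPS30
mcc	DBT
mcc	PRPF19
mcc	MRPL10
mcc	RPL23L
mcc	VDAC1
mcc	ACAA2
mcc	PML
mcc	EIF3K
mcc	RPS23
mcc	RPS18
mcc	STUB1
mcc	GNA11
mcc	MLYCD
mnc	ALYREF
mnc	HNRNPL
mnc	PRPF19
mnc	HNRNPM
mnc	MRPL10
mnc	RPL23L
mnc	MRPS30
mnc	EIF3K
mnc	RPS23
mnc	RPS18
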