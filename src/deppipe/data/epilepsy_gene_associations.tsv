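gene	disease_id	disease_name	channel	score
ATP6V1A	DOID:1826	Epilepsy	knowledge	4
GLS	DOID:1826	Epilepsy	knowledge	4
GLUL	DOID:1826	Epilepsy	textmining	2.507
GJA1	DOID:1826	Epilepsy	textmining	2.483
MBP	DOID:1826	Epilepsy	textmining	2.404
GLUL	DOID:3328	Temporal lobe epilepsy	textmining	2.37
GLUL	DOID:2234	Focal epilepsy	textmining	2.34
GSR	DOID:1826	Epilepsy	textmining	2.23
FAAH	DOID:1826	Epilepsy	textmining	2.212
HSPA4	DOID:1826	Epilepsy	textmining	2.142
NCAN	DOID:1826	Epilepsy	textmining	2.067
GJA1	DOID:2234	Focal epilepsy	textmining	2.018
GJA1	DOID:3328	Temporal lobe epilepsy	textmining	2.006
BCAN	DOID:1826	Epilepsy	textmining	2.003
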