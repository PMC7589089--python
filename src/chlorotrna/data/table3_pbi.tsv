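virus	clade	position	column_label	amino_acid	codon	spacer_to_next	orphan	orphan_distance_nt	intron	pseudogene	note	printed_total
Fr5L	Pbi	1	Phe	Phe	UUC	23	0		0	0		11
Fr5L	Pbi	2	Arg	Arg	AGA	3	0		0	0		11
Fr5L	Pbi	3	Gly	Gly	GGA	22	0		0	0		11
Fr5L	Pbi	4	Asn-1	Asn	AAC	22	0		0	0		11
Fr5L	Pbi	5	Tyr-1	Tyr	UAC	2	0		1	0		11
Fr5L	Pbi	6	Asn-2	Asn	AAC	25	0		0	0		11
Fr5L	Pbi	7	Asn-3	Asn	AAC	22	0		0	0		11
Fr5L	Pbi	8	Tyr-2	Tyr	UAC	22	0		1	0		11
Fr5L	Pbi	9	Lys-2	Lys	AAG	2	0		0	0		11
Fr5L	Pbi	10	Thr-1	Thr	ACG	245	0		0	0		11
Fr5L	Pbi	11	Thr-2	Thr	ACG		0		0	0		11
CZ-2	Pbi	1	Arg	Arg	AGA	23	0		0	0		10
CZ-2	Pbi	2	Gly	Gly	GGA	3	0		0	0		10
CZ-2	Pbi	3	Asn-1	Asn	AAC	22	0		0	0		10
CZ-2	Pbi	4	Tyr-1	Tyr	UAC	23	0		1	0		10
CZ-2	Pbi	5	Lys-1	Lys	AAG	23	0		0	0		10
CZ-2	Pbi	6	Asn-2	Asn	AAC	22	0		0	0		10
CZ-2	Pbi	7	Asn-3	Asn	AAC	22	0		0	0		10
CZ-2	Pbi	8	Asn-4	Asn	AAC	2	0		0	0		10
CZ-2	Pbi	9	Lys-2	Lys	AAG	243	0		0	0		10
CZ-2	Pbi	10	Thr-1	Thr	ACG		0		0	0		10
MT325	Pbi	1	Ile	Ile	AUA	24	0		0	0		10
MT325	Pbi	2	Leu	Leu	UUA	24	0		0	0		10
MT325	Pbi	3	Phe	Phe	UUC	23	0		0	0		10
MT325	Pbi	4	Arg	Arg	AGA	3	0		0	0		10
MT325	Pbi	5	Gly	Gly	GGA	23	0		0	0		10
MT325	Pbi	6	Asn-1	Asn	AAC	22	0		0	0		10
MT325	Pbi	7	Tyr-1	Tyr	UAC	22	0		1	0		10
MT325	Pbi	8	Asn-3	Asn	AAC	2	0		0	0		10
MT325	Pbi	9	Lys-2	Lys	AAG	161	0		0	0		10
MT325	Pbi	10	Thr-1	Thr	ACG		0		0	0		10
Can18-4	Pbi	1	Ile	Ile	AUA	24	0		0	0		10
Can18-4	Pbi	2	Leu	Leu	UUA	24	0		0	0		10
Can18-4	Pbi	3	Phe	Phe	UUC	23	0		0	0		10
Can18-4	Pbi	4	Arg	Arg	AGA	3	0		0	0		10
Can18-4	Pbi	5	Gly	Gly	GGA	23	0		0	0		10
Can18-4	Pbi	6	Asn-1	Asn	AAC	22	0		0	0		10
Can18-4	Pbi	7	Tyr-1	Tyr	UAC	22	0		1	0		10
Can18-4	Pbi	8	Asn-3	Asn	AAC	2	0		0	0		10
Can18-4	Pbi	9	Lys-2	Lys	AAG	1041	0		0	0		10
Can18-4	Pbi	10	Thr-1	Thr	ACG		0		0	0		10
CVB-1	Pbi	1	Ile	Ile	AUA	24	0		0	0		10
CVB-1	Pbi	2	Leu	Leu	UUA	24	0		0	0		10
CVB-1	Pbi	3	Phe	Phe	UUC	26	0		0	0		10
CVB-1	Pbi	4	Arg	Arg	AGA	985	0		0	0		10
CVB-1	Pbi	5	Gly	Gly	GGA	24	0		0	0		10
CVB-1	Pbi	6	Asn-1	Asn	AAC	23	0		0	0		10
CVB-1	Pbi	7	Tyr-1	Tyr	UAC	22	0		1	0		10
CVB-1	Pbi	8	Asn-3	Asn	AAC	2	0		0	0		10
CVB-1	Pbi	9	Lys-2	Lys	AAG	161	0		0	0		10
CVB-1	Pbi	10	Thr-1	Thr	ACG		0		0	0		10
FR483	Pbi	1	Ile	Ile	AUA	22	0		0	0		9
FR483	Pbi	2	Leu	Leu	UUA	24	0		0	0		9
FR483	Pbi	3	Arg	Arg	AGA	3	0		0	0		9
FR483	Pbi	4	Gly	Gly	GGA	23	0		0	0		9
FR483	Pbi	5	Asn-1	Asn	AAC	23	0		0	0		9
FR483	Pbi	6	Tyr-1	Tyr	UAC	22	0		1	0		9
FR483	Pbi	7	Asn-3	Asn	AAC	2	0		0	0		9
FR483	Pbi	8	Lys-2	Lys	AAG	161	0		0	0		9
FR483	Pbi	9	Thr-1	Thr	ACG		0		0	0		9
CVG-1	Pbi	1	Ile	Ile	AUA	132	0		0	0		9
CVG-1	Pbi	2	Phe	Phe	UUC	23	0		0	0		9
CVG-1	Pbi	3	Arg	Arg	AGA	3	0		0	0		9
CVG-1	Pbi	4	Gly	Gly	GGA	23	0		0	0		9
CVG-1	Pbi	5	Asn-1	Asn	AAC	23	0		0	0		9
CVG-1	Pbi	6	Tyr-1	Tyr	UAC	22	0		1	0		9
CVG-1	Pbi	7	Asn-3	Asn	AAC	2	0		0	0		9
CVG-1	Pbi	8	Lys-2	Lys	AAG	161	0		0	0		9
CVG-1	Pbi	9	Thr-1	Thr	ACG		0		0	0		9
CVR-1	Pbi	1	Ile	Ile	AUA	132	0		0	0		9
CVR-1	Pbi	2	Phe	Phe	UUC	23	0		0	0		9
CVR-1	Pbi	3	Arg	Arg	AGA	3	0		0	0		9
CVR-1	Pbi	4	Gly	Gly	GGA	23	0		0	0		9
CVR-1	Pbi	5	Asn-1	Asn	AAC	23	0		0	0		9
CVR-1	Pbi	6	Tyr-1	Tyr	UAC	22	0		1	0		9
CVR-1	Pbi	7	Asn-3	Asn	AAC	2	0		0	0		9
CVR-1	Pbi	8	Lys-2	Lys	AAG	159	0		0	0		9
CVR-1	Pbi	9	Thr-1	Thr	ACG		0		0	0		9
CVA-1	Pbi	1	Ile	Ile	AUA	132	0		0	0		9
CVA-1	Pbi	2	Phe	Phe	UUC	23	0		0	0		9
CVA-1	Pbi	3	Arg	Arg	AGA	3	0		0	0		9
CVA-1	Pbi	4	Gly	Gly	GGA	23	0		0	0		9
CVA-1	Pbi	5	Asn-1	Asn	AAC	23	0		0	0		9
CVA-1	Pbi	6	Tyr-1	Tyr	UAC	22	0		1	0		9
CVA-1	Pbi	7	Asn-3	Asn	AAC	2	0		0	0		9
CVA-1	Pbi	8	Lys-2	Lys	AAG	159	0		0	0		9
CVA-1	Pbi	9	Thr-1	Thr	ACG		0		0	0		9
AP110A	Pbi	1	Ile	Ile	AUA	132	0		0	0		9
AP110A	Pbi	2	Phe	Phe	UUC	23	0		0	0		9
AP110A	Pbi	3	Arg	Arg	AGA	3	0		0	0		9
AP110A	Pbi	4	Gly	Gly	GGA	23	0		0	0		9
AP110A	Pbi	5	Asn-1	Asn	AAC	23	0		0	0		9
AP110A	Pbi	6	Tyr-1	Tyr	UAC	23	0		1	0		9
AP110A	Pbi	7	Asn-3	Asn	AAC	2	0		0	0		9
AP110A	Pbi	8	Lys-2	Lys	AAG	159	0		0	0		9
AP110A	Pbi	9	Thr-1	Thr	ACG		0		0	0		9
CVM-1	Pbi	1	Ile	Ile	AUA	132	0		0	0		9
CVM-1	Pbi	2	Phe	Phe	UUC	23	0		0	0		9
CVM-1	Pbi	3	Arg	Arg	AGA	3	0		0	0		9
CVM-1	Pbi	4	Gly	Gly	GGA	24	0		0	0		9
CVM-1	Pbi	5	Asn-1	Asn	AAC	96	0		0	0		9
CVM-1	Pbi	6	Tyr-1	Tyr	UAC	22	0		1	0		9
CVM-1	Pbi	7	Asn-3	Asn	AAC	2	0		0	0		9
CVM-1	Pbi	8	Lys-2	Lys	AAG	161	0		0	0		9
CVM-1	Pbi	9	Thr-1	Thr	ACG		0		0	0		9
NW665.2	Pbi	1	Ile	Ile	AUA	1142	0		0	0		8
NW665.2	Pbi	2	Arg	Arg	AGA	3	0		0	0		8
NW665.2	Pbi	3	Gly	Gly	GGA	23	0		0	0		8
NW665.2	Pbi	4	Asn-1	Asn	AAC	23	0		0	0		8
NW665.2	Pbi	5	Tyr-1	Tyr	UAC	22	0		1	0		8
NW665.2	Pbi	6	Asn-3	Asn	AAC	2	0		0	0		8
NW665.2	Pbi	7	Lys-2	Lys	AAG	161	0		0	0		8
NW665.2	Pbi	8	Thr-1	Thr	ACG		0		0	0		8
OR0704.2.2	Pbi	1	Arg	Arg	AGA	3	0		0	0		7
OR0704.2.2	Pbi	2	Gly	Gly	GGA	23	0		0	0		7
OR0704.2.2	Pbi	3	Asn-1	Asn	AAC	22	0		0	0		7
OR0704.2.2	Pbi	4	Tyr-1	Tyr	UAC	22	0		1	0		7
OR0704.2.2	Pbi	5	Asn-3	Asn	AAC	2	0		0	0		7
OR0704.2.2	Pbi	6	Lys-2	Lys	AAG	159	0		0	0		7
OR0704.2.2	Pbi	7	Thr-1	Thr	ACG		0		0	0		7
NE-JV-1	Pbi	1	Ile	Ile	AUA	132	0		0	0		3
NE-JV-1	Pbi	2	Leu	Leu	UUA	1416	0		0	0		3
NE-JV-1	Pbi	3	Arg	Arg	AGA		0		0	0		3
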