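virus	clade	position	column_label	amino_acid	codon	spacer_to_next	orphan	orphan_distance_nt	intron	pseudogene	note	printed_total
MA-1E	NC64A	1	Leu-1	Leu	UUG	25	0		0	0		14
MA-1E	NC64A	2	Ile	Ile	AUA	23	0		0	0		14
MA-1E	NC64A	3	Asn-1	Asn	AAC	24	0		0	0		14
MA-1E	NC64A	4	Leu-2	Leu	UUA	3	0		0	0		14
MA-1E	NC64A	5	Arg-1	Arg	AGA	23	0		0	0		14
MA-1E	NC64A	6	Asn-2	Asn	AAC	3	0		0	0		14
MA-1E	NC64A	7	Gly	Gly	GGA	27	0		0	0		14
MA-1E	NC64A	8	Asn-3	Asn	AAC	3	0		0	0		14
MA-1E	NC64A	9	Lys-1	Lys	AAG	22	0		0	0		14
MA-1E	NC64A	10	Gln	Gln	CAG	23	0		0	0		14
MA-1E	NC64A	11	Lys-2	Lys	AAG	23	0		0	0		14
MA-1E	NC64A	12	Tyr	Tyr	UAC	30	0		1	0		14
MA-1E	NC64A	13	Lys-3	Lys	AAA	1	0		0	0		14
MA-1E	NC64A	14	Lys-4	Lys	AAG		0		0	0		14
CvsA1	NC64A	1	Leu-1	Leu	UUG	25	0		0	0		14
CvsA1	NC64A	2	Ile	Ile	AUA	23	0		0	0		14
CvsA1	NC64A	3	Asn-1	Asn	AAC	24	0		0	0		14
CvsA1	NC64A	4	Leu-2	Leu	UUA	3	0		0	0		14
CvsA1	NC64A	5	Arg-1	Arg	AGA	23	0		0	0		14
CvsA1	NC64A	6	Asn-2	Asn	AAC	3	0		0	0		14
CvsA1	NC64A	7	Gly	Gly	GGA	27	0		0	0		14
CvsA1	NC64A	8	Asn-3	Asn	AAC	3	0		0	0		14
CvsA1	NC64A	9	Lys-1	Lys	AAG	22	0		0	0		14
CvsA1	NC64A	10	Gln	Gln	CAG	23	0		0	0		14
CvsA1	NC64A	11	Lys-2	Lys	AAG	23	0		0	0		14
CvsA1	NC64A	12	Tyr	Tyr	UAC	30	0		1	0		14
CvsA1	NC64A	13	Lys-3	Lys	AAA	1	0		0	0		14
CvsA1	NC64A	14	Lys-4	Lys	AAG		0		0	0		14
CviK1	NC64A	1	Leu-1	Leu	UUG	25	0		0	0		14
CviK1	NC64A	2	Ile	Ile	AUA	23	0		0	0		14
CviK1	NC64A	3	Asn-1	Asn	AAC	24	0		0	0		14
CviK1	NC64A	4	Leu-2	Leu	UUA	3	0		0	0		14
CviK1	NC64A	5	Arg-1	Arg	AGA	23	0		0	0		14
CviK1	NC64A	6	Asn-2	Asn	AAC	3	0		0	0		14
CviK1	NC64A	7	Gly	Gly	GGA	27	0		0	0		14
CviK1	NC64A	8	Asn-3	Asn	AAC	3	0		0	0		14
CviK1	NC64A	9	Lys-1	Lys	AAG	22	0		0	0		14
CviK1	NC64A	10	Gln	Gln	CAG	23	0		0	0		14
CviK1	NC64A	11	Lys-2	Lys	AAG	23	0		0	0		14
CviK1	NC64A	12	Tyr	Tyr	UAC	30	0		1	0		14
CviK1	NC64A	13	Lys-3	Lys	AAA	1	0		0	0		14
CviK1	NC64A	14	Lys-4	Lys	AAG		0		0	0		14
KS1B	NC64A	1	Leu-1	Leu	UUG	3	0		0	0		12
KS1B	NC64A	2	Ile	Ile	AUA	23	0		0	0		12
KS1B	NC64A	3	Asn-1	Asn	AAC	109	0		0	0		12
KS1B	NC64A	4	Leu-2	Leu	UUA	3	0		0	0		12
KS1B	NC64A	5	Arg-1	Arg	AGA	23	0		0	0		12
KS1B	NC64A	6	Asn-2	Asn	AAC	3	0		0	0		12
KS1B	NC64A	7	Gly	Gly	GGA	27	0		0	0		12
KS1B	NC64A	8	Asn-3	Asn	AAC	3	0		0	0		12
KS1B	NC64A	9	Lys-1	Lys	AAG	22	0		0	0		12
KS1B	NC64A	10	Gln	Gln	CAG	23	0		0	0		12
KS1B	NC64A	11	Tyr	Tyr	UAC	23	0		1	0		12
KS1B	NC64A	12	Lys-3	Lys	AAA		0		0	0		12
PBCV-1	NC64A	1	Leu-1	Leu	UUG	25	0		0	0		11
PBCV-1	NC64A	2	Ile	Ile	AUA	23	0		0	0		11
PBCV-1	NC64A	3	Asn-1	Asn	AAC	23	0		0	0		11
PBCV-1	NC64A	4	Leu-2	Leu	UUA	3	0		0	0		11
PBCV-1	NC64A	5	Arg-1	Arg	AGA	24	0		0	0		11
PBCV-1	NC64A	6	Asn-2	Asn	AAC	3	0		0	0		11
PBCV-1	NC64A	7	Gly	Lys	AAG	24	0		0	0	tRNA-Lys substituted for tRNA-Gly (footnote b)	11
PBCV-1	NC64A	8	Asn-3	Asn	AAC	22	0		0	0		11
PBCV-1	NC64A	9	Lys-1	Lys	AAG	23	0		0	0		11
PBCV-1	NC64A	10	Tyr	Tyr	UAC	33	0		1	0		11
PBCV-1	NC64A	11	Lys-3	Lys	AAA		0		0	0		11
IL-3A	NC64A	1	Leu-1	Leu	UUG	25	0		0	0		10
IL-3A	NC64A	2	Ile	Ile	AUA	23	0		0	0		10
IL-3A	NC64A	3	Asn-1	Asn	AAC	24	0		0	0		10
IL-3A	NC64A	4	Leu-2	Leu	UUA	3	0		0	0		10
IL-3A	NC64A	5	Arg-1	Arg	AGA	23	0		0	0		10
IL-3A	NC64A	6	Asn-2	Asn	AAC	3	0		0	0		10
IL-3A	NC64A	7	Gly	Gly	GGA	25	0		0	0		10
IL-3A	NC64A	8	Lys-1	Lys	AAG	3	0		0	0		10
IL-3A	NC64A	9	Gln	Asn	AAC	84	0		0	0	tRNA-Asn substituted for tRNA-Gln (footnote c)	10
IL-3A	NC64A	10	Tyr	Tyr	UAC		0		1	0		10
MA-1D	NC64A	1	Leu-1	Leu	UUG	25	0		0	0		12
MA-1D	NC64A	2	Ile	Ile	AUA	23	0		0	0		12
MA-1D	NC64A	3	Asn-1	Asn	AAC	24	0		0	0		12
MA-1D	NC64A	4	Leu-2	Leu	UUA	5	0		0	0		12
MA-1D	NC64A	5	Arg-1	Arg	AGA	15	0		0	0		12
MA-1D	NC64A	6	Asn-2	Asn	AAC	3	0		0	0		12
MA-1D	NC64A	7	Gly	Gly	GGA	25	0		0	0		12
MA-1D	NC64A	8	Lys-1	Lys	AAG	3	0		0	0		12
MA-1D	NC64A	9	Tyr	Tyr	UAC	22	0		1	0		12
MA-1D	NC64A	10	Arg-2	Arg	AGA	23	0		0	0		12
MA-1D	NC64A	11	Asp	Asp	GAC	33	0		0	0		12
MA-1D	NC64A	12	Val	Val	GUU		0		0	0		12
NE-JV-4	NC64A	1	Leu-1	Leu	UUG	25	0		0	0		11
NE-JV-4	NC64A	2	Ile	Ile	AUA	23	0		0	0		11
NE-JV-4	NC64A	3	Asn-1	Asn	AAC	24	0		0	0		11
NE-JV-4	NC64A	4	Leu-2	Leu	UUA	3	0		0	0		11
NE-JV-4	NC64A	5	Arg-1	Arg	AGA	23	0		0	0		11
NE-JV-4	NC64A	6	Asn-2	Asn	AAC	3	0		0	0		11
NE-JV-4	NC64A	7	Gly	Gly	GGA	72	0		0	0		11
NE-JV-4	NC64A	8	Asn-3	Asn	AAC	3	0		0	0		11
NE-JV-4	NC64A	9	Lys-1	Lys	AAG	23	0		0	0		11
NE-JV-4	NC64A	10	Gln	Asn	AAC	33	0		0	0	tRNA-Asn substituted for tRNA-Gln (footnote c)	11
NE-JV-4	NC64A	11	Arg-2	Arg	AGA		0		0	0		11
AN69C	NC64A	1	Leu-1	Leu	UUG	25	0		0	0		10
AN69C	NC64A	2	Ile	Ile	AUA	23	0		0	0		10
AN69C	NC64A	3	Asn-1	Asn	AAC	24	0		0	0		10
AN69C	NC64A	4	Leu-2	Leu	UUA	3	0		0	0		10
AN69C	NC64A	5	Arg-1	Arg	AGA	23	0		0	0		10
AN69C	NC64A	6	Asn-2	Asn	AAC	3	0		0	0		10
AN69C	NC64A	7	Gly	Gly	GGA	12	0		0	0		10
AN69C	NC64A	8	Lys-1	Lys	AAG	22	0		0	0		10
AN69C	NC64A	9	Gln	Gln	CAG	23	0		0	0		10
AN69C	NC64A	10	Tyr	Tyr	UAC		0		1	0		10
NY-2B	NC64A	1	Leu-1	Leu	UUG	25	0		0	0		8
NY-2B	NC64A	2	Ile	Ile	AUA	23	0		0	0		8
NY-2B	NC64A	3	Asn-1	Asn	AAC	23	0		0	0		8
NY-2B	NC64A	4	Leu-2	Leu	UUA	3	0		0	0		8
NY-2B	NC64A	5	Arg-1	Arg	AGA	23	0		0	0		8
NY-2B	NC64A	6	Gly	Gly	GGA	22	0		0	0		8
NY-2B	NC64A	7	Lys-1	Lys	AAG	2	0		0	0		8
NY-2B	NC64A	8	Tyr	Tyr	UAC		0		1	0		8
IL-5-2s1	NC64A	1	Leu-1	Leu	UUG	25	0		0	0		8
IL-5-2s1	NC64A	2	Ile	Ile	AUA	23	0		0	0		8
IL-5-2s1	NC64A	3	Asn-1	Asn	AAC	23	0		0	0		8
IL-5-2s1	NC64A	4	Leu-2	Leu	UUA	3	0		0	0		8
IL-5-2s1	NC64A	5	Arg-1	Arg	AGA	23	0		0	0		8
IL-5-2s1	NC64A	6	Gly	Gly	GGA	22	0		0	0		8
IL-5-2s1	NC64A	7	Lys-1	Lys	AAG	2	0		0	0		8
IL-5-2s1	NC64A	8	Tyr	Tyr	UAC		0		1	0		8
NY-2A	NC64A	1	Leu-1	Leu	UUG	142	0		0	0		8
NY-2A	NC64A	2	Asn-1	Asn	AAC	23	0		0	0		8
NY-2A	NC64A	3	Leu-2	Leu	UUA	3	0		0	0		8
NY-2A	NC64A	4	Arg-1	Arg	AGA	24	0		0	0		8
NY-2A	NC64A	5	Asn-2	Asn	AAC	22	0		0	0		8
NY-2A	NC64A	6	Gly	Gly	GGA	2	0		0	0		8
NY-2A	NC64A	7	Lys-1	Lys	AAG	25	0		0	0		8
NY-2A	NC64A	8	Lys-3	Lys	AAA		0		0	0		8
NYs-1	NC64A	1	Leu-1	Leu	UUG	25	0		0	0		8
NYs-1	NC64A	2	Ile	Ile	AUA	25	0		0	0		8
NYs-1	NC64A	3	Asn-1	Asn	AAC	229	0		0	0		8
NYs-1	NC64A	4	Arg-1	Arg	AGA	3	0		0	0		8
NYs-1	NC64A	5	Asn-2	Asn	AAC	1058	0		0	0		8
NYs-1	NC64A	6	Gly	Gly	GGA	2	0		0	0		8
NYs-1	NC64A	7	Lys-1	Lys	AAG	25	0		0	0		8
NYs-1	NC64A	8	Lys-3	Lys	AAA		0		0	0		8
AR158	NC64A	1	Leu-1	Leu	UUG	25	0		0	0		7
AR158	NC64A	2	Ile	Ile	AUA	25	0		0	0		7
AR158	NC64A	3	Asn-1	Asn	AAC	51	0		0	0		7
AR158	NC64A	4	Leu-2	Leu	UUA	23	0		0	0		7
AR158	NC64A	5	Arg-1	Arg	AGA	3	0		0	0		7
AR158	NC64A	6	Asn-2	Asn	AAC	24	0		0	0		7
AR158	NC64A	7	Gly	Gly	GGA		0		0	0		7
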