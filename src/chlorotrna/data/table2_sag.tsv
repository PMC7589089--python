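virus	clade	position	column_label	amino_acid	codon	spacer_to_next	orphan	orphan_distance_nt	intron	pseudogene	note	printed_total
Can0610SP	SAG	1	Ser	Ser	AGU	4	0		0	0		13
Can0610SP	SAG	2	Arg	Arg	AGA	25	0		0	0		13
Can0610SP	SAG	3	Asn-1	Asn	AAC	22	0		0	0		13
Can0610SP	SAG	4	Gly	Gly	GGA	22	0		0	0		13
Can0610SP	SAG	5	Ile-2	Ile	AUU	25	0		0	0		13
Can0610SP	SAG	6	Asn-2	Asn	AAC	23	0		0	0		13
Can0610SP	SAG	7	Met	Met	AUG	22	0		0	0		13
Can0610SP	SAG	8	Asp-1	Asp	GAC	22	0		0	0		13
Can0610SP	SAG	9	Asn-3	Asn	AAC	2	0		0	0		13
Can0610SP	SAG	10	Tyr	Tyr	UAC	21	0		1	0		13
Can0610SP	SAG	11	Lys	Lys	AAG	4	0		0	0		13
Can0610SP	SAG	12	Asn-4	Asn	AAC		0		0	0		13
Can0610SP	SAG	13	Thr	Thr	ACU		1	36000	0	0	orphan tRNA downstream of the cluster	13
OR0704.3	SAG	1	Ser	Ser	AGU	4	0		0	0		13
OR0704.3	SAG	2	Arg	Arg	AGA	25	0		0	0		13
OR0704.3	SAG	3	Asn-1	Asn	AAC	22	0		0	0		13
OR0704.3	SAG	4	Gly	Gly	GGA	22	0		0	0		13
OR0704.3	SAG	5	Ile-2	Ile	AUU	25	0		0	0		13
OR0704.3	SAG	6	Asn-2	Asn	AAC	23	0		0	0		13
OR0704.3	SAG	7	Met	Met	AUG	22	0		0	0		13
OR0704.3	SAG	8	Asp-1	Asp	GAC	22	0		0	0		13
OR0704.3	SAG	9	Asn-3	Asn	AAC	2	0		0	0		13
OR0704.3	SAG	10	Tyr	Tyr	UAC	21	0		1	0		13
OR0704.3	SAG	11	Lys	Lys	AAG	148	0		0	0		13
OR0704.3	SAG	12	Leu-1	Leu	UUA		0		0	0		13
OR0704.3	SAG	13	Thr	Thr	ACU		1	32000	0	0	orphan tRNA downstream of the cluster	13
NE-JV-2	SAG	1	Ile-1	Ile	AUA	22	0		0	0		13
NE-JV-2	SAG	2	Ser	Ser	AGU	4	0		0	0		13
NE-JV-2	SAG	3	Arg	Arg	AGA	25	0		0	0		13
NE-JV-2	SAG	4	Asn-1	Asn	AAC	22	0		0	0		13
NE-JV-2	SAG	5	Gly	Gly	GGA	22	0		0	0		13
NE-JV-2	SAG	6	Ile-2	Ile	AUU	22	0		0	0		13
NE-JV-2	SAG	7	Asn-2	Asn	AAC	23	0		0	0		13
NE-JV-2	SAG	8	Met	Met	AUG	22	0		0	0		13
NE-JV-2	SAG	9	Asn-3	Asn	AAC	2	0		0	0		13
NE-JV-2	SAG	10	Tyr	Tyr	UAC	21	0		1	0		13
NE-JV-2	SAG	11	Lys	Lys	AAG	148	0		0	0		13
NE-JV-2	SAG	12	Leu-1	Leu	UUA		0		0	0		13
NE-JV-2	SAG	13	Thr	Thr	ACU		1	29000	0	0	orphan tRNA downstream of the cluster	13
NE-JV-3	SAG	1	Ser	Ser	AGU	4	0		0	0		12
NE-JV-3	SAG	2	Arg	Arg	AGA	25	0		0	0		12
NE-JV-3	SAG	3	Asn-1	Asn	AAC	22	0		0	0		12
NE-JV-3	SAG	4	Gly	Gly	GGA	22	0		0	0		12
NE-JV-3	SAG	5	Ile-2	Ile	AUU	22	0		0	0		12
NE-JV-3	SAG	6	Asn-2	Asn	AAC	23	0		0	0		12
NE-JV-3	SAG	7	Met	Met	AUG	22	0		0	0		12
NE-JV-3	SAG	8	Asn-3	Asn	AAC	2	0		0	0		12
NE-JV-3	SAG	9	Tyr	Tyr	UAC	21	0		1	0		12
NE-JV-3	SAG	10	Lys	Lys	AAG	148	0		0	0		12
NE-JV-3	SAG	11	Leu-1	Leu	UUA		0		0	0		12
NE-JV-3	SAG	12	Thr	Thr	ACU		1	31000	0	0	orphan tRNA downstream of the cluster	12
ATCV-1	SAG	1	Ser	Ser	AGU	5	0		0	0		11
ATCV-1	SAG	2	Arg	Arg	AGA	25	0		0	0		11
ATCV-1	SAG	3	Asn-1	Asn	AAC	22	0		0	0		11
ATCV-1	SAG	4	Gly	Gly	GGA	23	0		0	0		11
ATCV-1	SAG	5	Ile-2	Ile	AUU	22	0		0	0		11
ATCV-1	SAG	6	Val-1	Val	GUU	22	0		0	0		11
ATCV-1	SAG	7	Val-2	Val	GUU	22	0		0	0		11
ATCV-1	SAG	8	Asn-3	Asn	AAC	2	0		0	0		11
ATCV-1	SAG	9	Tyr	Tyr	UAC	22	0		1	0		11
ATCV-1	SAG	10	Lys	Lys	AAG		0		0	0		11
ATCV-1	SAG	11	Thr	Thr	ACU		1	31000	0	0	orphan tRNA downstream of the cluster	11
WI0606	SAG	1	Ser	Ser	AGU	4	0		0	0		11
WI0606	SAG	2	Arg	Arg	AGA	25	0		0	0		11
WI0606	SAG	3	Asn-1	Asn	AAC	22	0		0	0		11
WI0606	SAG	4	Gly	Gly	GGA	23	0		0	0		11
WI0606	SAG	5	Ile-2	Ile	AUU	22	0		0	0		11
WI0606	SAG	6	Val-2	Val	GUU	22	0		0	0		11
WI0606	SAG	7	Asn-3	Asn	AAC	2	0		0	0		11
WI0606	SAG	8	Tyr	Tyr	UAC	22	0		1	0		11
WI0606	SAG	9	Lys	Lys	AAG	148	0		0	0		11
WI0606	SAG	10	Leu-1	Leu	UUA		0		0	0		11
WI0606	SAG	11	Thr	Thr	ACU		1	31000	0	0	orphan tRNA downstream of the cluster	11
MO0605SPH	SAG	1	Ser	Ser	AGU	4	0		0	0		11
MO0605SPH	SAG	2	Arg	Arg	AGA	25	0		0	0		11
MO0605SPH	SAG	3	Asn-1	Asn	AAC	22	0		0	0		11
MO0605SPH	SAG	4	Gly	Gly	GGA	23	0		0	0		11
MO0605SPH	SAG	5	Ile-2	Ile	AUU	22	0		0	0		11
MO0605SPH	SAG	6	Val-2	Val	GUU	22	0		0	0		11
MO0605SPH	SAG	7	Asn-3	Asn	AAC	2	0		0	0		11
MO0605SPH	SAG	8	Tyr	Tyr	UAC	22	0		1	0		11
MO0605SPH	SAG	9	Lys	Lys	AAG	148	0		0	0		11
MO0605SPH	SAG	10	Leu-1	Leu	UUA		0		0	0		11
MO0605SPH	SAG	11	Thr	Thr	ACU		1	30000	0	0	orphan tRNA downstream of the cluster	11
GM0701.1	SAG	1	Arg	Arg	AGA	25	0		0	0		10
GM0701.1	SAG	2	Asn-1	Asn	AAC	1	0		0	0		10
GM0701.1	SAG	3	Gly	Gly	GGA	22	0		0	0		10
GM0701.1	SAG	4	Ile-2	Ile	AUU	24	0		0	0		10
GM0701.1	SAG	5	Asn-2	Asn	AAC	23	0		0	0		10
GM0701.1	SAG	6	Asp-1	Asp	GAC	148	0		0	0		10
GM0701.1	SAG	7	Leu-1	Leu	UUA	77	0		0	0		10
GM0701.1	SAG	8	Asn-5	Asn	AAC	4	0		0	0		10
GM0701.1	SAG	9	Leu-2	Leu	UUG		0		0	0		10
GM0701.1	SAG	10	Thr	Thr	ACU		1	35000	0	0	orphan tRNA downstream of the cluster	10
Br0604L	SAG	1	Ser	Ser	AGU	4	0		0	0		9
Br0604L	SAG	2	Arg	Arg	AGA	25	0		0	0		9
Br0604L	SAG	3	Asn-1	Asn	AAC	22	0		0	0		9
Br0604L	SAG	4	Gly	Gly	GGA	25	0		0	0		9
Br0604L	SAG	5	Asn-2	Asn	AAC	23	0		0	0		9
Br0604L	SAG	6	Asn-3	Asn	AAC	2	0		0	0		9
Br0604L	SAG	7	Tyr	Tyr	UAC	242	0		1	0		9
Br0604L	SAG	8	Lys	Lys	AAG		0		0	0		9
Br0604L	SAG	9	Thr	Thr	ACU		1	32000	0	0	orphan tRNA downstream of the cluster	9
TN603.4.2	SAG	1	Arg	Arg	AGA	25	0		0	0		9
TN603.4.2	SAG	2	Asn-1	Asn	AAC	22	0		0	0		9
TN603.4.2	SAG	3	Gly	Gly	GGA	24	0		0	0		9
TN603.4.2	SAG	4	Asn-2	Asn	AAC	23	0		0	0		9
TN603.4.2	SAG	5	Asn-3	Asn	AAC	2	0		0	0		9
TN603.4.2	SAG	6	Tyr	Tyr	UAC	22	0		1	0		9
TN603.4.2	SAG	7	Lys	Lys	AAG	227	0		0	0		9
TN603.4.2	SAG	8	Leu-1	Leu	UUA		0		0	0		9
TN603.4.2	SAG	9	Thr	Thr	ACU		1	32000	0	0	orphan tRNA downstream of the cluster	9
Canal-1	SAG	1	Ile-1	Ile	AUA	158	0		0	0		9
Canal-1	SAG	2	Ser	Ser	AGU	5	0		0	0		9
Canal-1	SAG	3	Arg	Arg	AGA	25	0		0	0		9
Canal-1	SAG	4	Asn-1	Asn	AAC	22	0		0	0		9
Canal-1	SAG	5	Gly	Gly	GGA	65	0		0	0		9
Canal-1	SAG	6	Met	Met	AUG	23	0		0	0		9
Canal-1	SAG	7	Tyr	Tyr	UAC	24	0		1	0		9
Canal-1	SAG	8	Lys	Lys	AAG		0		0	0		9
Canal-1	SAG	9	Thr	Thr	ACU		1	29000	0	0	orphan tRNA downstream of the cluster	9
MN0810.1	SAG	1	Ser	Ser	AGU	23	0		0	0		9
MN0810.1	SAG	2	Arg	Arg	AGA	24	0		0	0		9
MN0810.1	SAG	3	Asn-1	Asn	AAC	1	0		0	0		9
MN0810.1	SAG	4	Gly	Gly	GGA	22	0		0	0		9
MN0810.1	SAG	5	Ile-2	Ile	AUU	22	0		0	0		9
MN0810.1	SAG	6	Asn-2	Asn	AAC	22	0		0	0		9
MN0810.1	SAG	7	Met	Met	AUG	4	0		0	0		9
MN0810.1	SAG	8	Asp-1	Asp	GAC		0		0	0		9
MN0810.1	SAG	9	Thr	Thr	ACU		1	35000	0	0	orphan tRNA downstream of the cluster	9
NTS-1	SAG	1	Arg	Arg	AGA	23	0		0	0		7
NTS-1	SAG	2	Asn-1	Asn	AAC	25	0		0	0		7
NTS-1	SAG	3	Gly	Gly	GGA	22	0		0	0		7
NTS-1	SAG	4	Asn-2	Asn	AAC	21	0		0	0		7
NTS-1	SAG	5	Tyr	Tyr	UAC	23	0		1	0		7
NTS-1	SAG	6	Lys	Lys	AAG		0		0	0		7
NTS-1	SAG	7	Thr	Thr	ACU		1	33000	0	0	orphan tRNA downstream of the cluster	7
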