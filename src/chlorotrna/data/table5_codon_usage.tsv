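codon	amino_acid	pbcv1	an69c	host	ratio_printed	bold
GCA	A	1.92	1.15	2.42	0.63	0
GCC	A	0.86	0.64	5.54	0.14	0
GCG	A	1.29	0.84	5.46	0.20	0
GCU	A	1.30	0.82	1.72	0.62	0
UGC	C	0.67	1.08	1.77	0.49	0
UGU	C	1.23	1.88	0.32	4.86	0
GAC	D	1.97	1.31	3.04	0.54	0
GAU	D	3.02	1.91	1.06	4.56	0
GAA	E	3.69	2.47	0.54	5.70	0
GAG	E	1.26	1.08	4.92	0.24	0
UUC	F	2.53	2.40	1.55	1.59	0
UUU	F	2.94	3.49	0.95	3.38	0
GGA	G	1.71	1.28	0.76	1.97	1
GGC	G	0.61	0.61	5.88	0.10	0
GGG	G	1.12	0.92	2.07	0.52	0
GGU	G	2.10	1.42	0.67	2.63	0
CAC	H	0.89	1.21	1.89	0.56	0
CAU	H	1.26	1.87	0.52	3.01	0
AUA	I	2.44	2.64	0.20	12.70	1
AUC	I	2.00	1.80	1.68	1.13	0
AUU	I	2.87	2.88	0.44	6.53	0
AAA	K	4.70	3.76	0.25	16.92	1
AAG	K	2.48	1.91	2.53	0.87	1
CUA	L	0.85	0.93	0.27	3.30	0
CUC	L	1.26	1.09	1.47	0.80	0
CUG	L	0.85	1.08	6.85	0.14	0
CUU	L	1.65	1.67	0.50	2.00	0
UUA	L	1.39	1.81	0.06	26.67	1
UUG	L	1.76	2.06	0.56	3.41	1
AUG	M	2.76	1.97	1.84	2.04	0
AAC	N	2.62	2.28	1.48	1.66	1
AAU	N	3.16	2.78	0.30	9.9	0
CCA	P	1.42	1.24	1.08	1.23	0
CCC	P	1.07	0.91	2.55	0.39	0
CCG	P	0.96	0.97	2.30	0.42	0
CCU	P	1.33	0.89	0.96	1.16	0
CAA	Q	1.84	2.09	0.59	3.33	0
CAG	Q	0.87	1.06	4.93	0.2	0
AGA	R	1.43	1.71	0.25	6.28	1
AGG	R	0.68	0.84	0.92	0.83	0
CGA	R	0.66	1.48	0.44	2.43	0
CGC	R	0.66	0.84	3.22	0.23	0
CGG	R	0.45	0.94	2.11	0.32	0
CGU	R	1.05	1.38	0.44	2.76	0
AGC	S	0.71	0.82	3.03	0.25	0
AGU	S	1.26	1.24	0.27	4.63	0
UCA	S	1.48	1.78	0.43	3.79	0
UCC	S	0.98	1.34	1.33	0.87	0
UCG	S	1.10	1.38	1.05	1.18	0
UCU	S	1.88	1.69	0.51	3.5	0
ACA	T	2.01	1.87	0.61	3.18	0
ACC	T	1.32	1.38	1.98	0.68	0
ACG	T	1.62	1.57	1.29	1.24	0
ACU	T	1.57	1.31	0.39	3.69	0
GUA	V	1.80	1.54	0.25	6.68	0
GUC	V	1.35	1.25	1.16	1.12	0
GUG	V	1.57	1.37	4.23	0.35	0
GUU	V	2.34	2.28	0.40	5.78	1
UGG	W	1.09	1.24	1.61	0.72	0
UAC	Y	1.52	1.46	1.42	1.05	1
UAU	Y	2.24	2.66	0.38	6.45	0
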