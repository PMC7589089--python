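trna	codon	nc64a	sag	pbi
Ile-1	AUA	c	c	c
Leu-1	UUA	c	c	c
Asn-1	AAC	c	c	c
Gly-1	GGA	c	c	c
Lys-1	AAG	c	c	c
Tyr-1	UAC	c	c	c
Arg-1	AGA	c	c	c
Asp-1	GAC	d	d	
Val-1	GUU	d	d	
Leu-2	UUG	d	d	
Gln-1	CAG	u		
Lys-2	AAA	u		
Ser-1	AGU		u	
Ile-2	AUU		u	
Met-1	AUG		u	
Thr-1	ACU		u	
Phe-1	UUC			u
Thr-1b	ACG			u
Thr-2b	ACG			u
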