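compound	gene_id	log_fold_change	inhibitor_exists	inhibitor_is_antibody	secreted	recombinant_exists	activator_exists	is_growth_factor	is_ecm	known_or_contradictory
WAY 170523	MMP13	1.9	True	False	False	False	False	False	False	False
EED226	SUZ12	1.2	True	False	False	False	False	False	False	False
APE1 Inhibitor III	APEX1	0.8	True	False	False	False	False	False	False	False
Silibinin	TMEM167A	1.5	True	False	False	False	False	False	False	False
Recombinant Netrin	UNC5B	-1.1	False	False	True	True	False	False	False	False
CINPA 1	CXADR	0.9	True	False	False	False	False	False	False	False
BITC	AGPS	1.3	True	False	False	False	False	False	False	False
AMZ-30	PME1	0.7	True	False	False	False	False	False	False	False
FDI-6	FOXM1	2.2	True	False	False	False	False	False	False	False
CPI-637	EP300	0.6	True	False	False	False	False	False	False	False
Anti-Galectin-9 Antibody	LGALS9	1.0	True	True	True	False	False	False	False	False
Recombinant Sonic Hedgehog/Shh	HHIP	1.1	False	False	False	True	False	False	False	False
C5OH	S100P	1.7	True	False	False	False	False	False	False	False
Recombinant C1qTNF1	C1QTNF1	-0.9	False	False	True	True	False	False	False	False
Recombinant Angiopoietin-like 4	ANGPTL4	-1.6	False	False	True	True	False	False	False	False
Recombinant CXCL5/ENA-7	CXCL5	-1.2	False	False	True	True	False	False	False	False
Recombinant Semaphorin 3C	SEMA3C	-0.8	False	False	True	True	False	False	False	False
Recombinant LTBP1	LTBP1	-1.4	False	False	True	True	False	False	False	False
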