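compartment	id	name	role	initial_conc_mM
extracellular	12-HETE		metabolite	1e-28
extracellular	12-HPETE		metabolite	1e-28
extracellular	13,14-dihydro-15-keto-PGE2		metabolite	1e-28
extracellular	15-HETE		metabolite	1e-28
extracellular	15-HPETE		metabolite	1e-28
extracellular	15-deoxy-PGJ2		metabolite	1e-28
extracellular	15-keto-PGE2		metabolite	1e-28
extracellular	5-HETE		metabolite	1e-28
extracellular	5-HPETE		metabolite	1e-28
extracellular	5-oxo-ETE		metabolite	1e-28
extracellular	6-keto-PGF1a		metabolite	1e-28
extracellular	6-trans-LTB4		metabolite	1e-28
extracellular	AA		metabolite	1e-28
extracellular	LTA4		metabolite	1e-28
extracellular	LTB4		metabolite	1e-28
extracellular	LTC4		metabolite	1e-28
extracellular	PGD2		metabolite	1e-28
extracellular	PGE2		metabolite	1e-28
extracellular	PGF2a		metabolite	1e-28
extracellular	PGH2		metabolite	1e-28
extracellular	PGI2		metabolite	1e-28
extracellular	PGJ2		metabolite	1e-28
extracellular	TXA2		metabolite	1e-28
extracellular	TXB2		metabolite	1e-28
intracellular	12-HETE		metabolite	1e-28
intracellular	12-HPETE		metabolite	1e-28
intracellular	12-LOX		enzyme	0.0
intracellular	13,14-dihydro-15-keto-PGE2		metabolite	1e-28
intracellular	15-HETE		metabolite	1e-28
intracellular	15-HPETE		metabolite	1e-28
intracellular	15-LOX		enzyme	0.0
intracellular	15-PGDH		enzyme	0.0
intracellular	15-deoxy-PGJ2		metabolite	1e-28
intracellular	15-keto-PGE2		metabolite	1e-28
intracellular	5-HEDH		enzyme	0.0
intracellular	5-HETE		metabolite	1e-28
intracellular	5-HPETE		metabolite	1e-28
intracellular	5-LOX		enzyme	0.0
intracellular	5-oxo-ETE		metabolite	1e-28
intracellular	6-keto-PGF1a		metabolite	1e-28
intracellular	6-trans-LTB4		metabolite	1e-28
intracellular	AA		metabolite	1e-28
intracellular	AA-source	unspecified AA source (release profile)	source	0.0
intracellular	ABC		transporter	0.0
intracellular	COX-1		enzyme	0.0
intracellular	COX-2		enzyme	0.0
intracellular	LTA4		metabolite	1e-28
intracellular	LTA4H		enzyme	0.0
intracellular	LTB4		metabolite	1e-28
intracellular	LTC4		metabolite	1e-28
intracellular	LTC4S		enzyme	0.0
intracellular	PGD2		metabolite	1e-28
intracellular	PGDS		enzyme	0.0
intracellular	PGE2		metabolite	1e-28
intracellular	PGES		enzyme	0.0
intracellular	PGF2a		metabolite	1e-28
intracellular	PGFS		enzyme	0.0
intracellular	PGH2		metabolite	1e-28
intracellular	PGI2		metabolite	1e-28
intracellular	PGIS		enzyme	0.0
intracellular	PGJ2		metabolite	1e-28
intracellular	PGT		transporter	0.0
intracellular	PHGPx		enzyme	0.0
intracellular	PLA2		enzyme	0.0
intracellular	PTGR2		enzyme	0.0
intracellular	TXA2		metabolite	1e-28
intracellular	TXAS		enzyme	0.0
intracellular	TXB2		metabolite	1e-28
intracellular	mem-AA	membrane-esterified AA pool	metabolite	1e-28
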