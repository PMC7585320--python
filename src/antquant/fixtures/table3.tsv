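accession	name	family	worker_antenna	male_antenna	worker_tibia	single_peptide
XP_011171049.1	TULIP	TULIP	0.49	0	0	
XP_011171041.1	TULIP	TULIP	0.35	0	0	
XP_011171091.1	TULIP	TULIP	0.35	0	0	
XP_025986354.1	TULIP	TULIP	0.20	0.28	0.11	
XP_011171044.1	TULIP	TULIP	0.06	0.04	0	worker_antenna
XP_011171046.1	TULIP	TULIP	0	0.56	0	
XP_011171043.1	TULIP	TULIP	0	0.10	0.04	
XP_011169150.1	TULIP	TULIP	0	0.05	0	male_antenna
XP_011171045.1	TULIP	TULIP	0	0.05	0	male_antenna
XP_011171034.1	TULIP	TULIP	0	0.04	0	male_antenna
XP_011162593.1	lipocalin	LIPOCALIN	0.16	0.05	0.08	
XP_011160582.1	lipocalin	LIPOCALIN	0.08	0	0	worker_antenna
XP_011166366.1	lipocalin	LIPOCALIN	0	0.05	0.04	worker_tibia
XP_011161896.1	NPC2	NPC2	0.29	0.69	0.035	worker_tibia
XP_011161897.1	NPC2	NPC2	0.31	0	0	
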