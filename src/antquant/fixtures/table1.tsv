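accession	name	family	worker_antenna	male_antenna	worker_tibia	single_peptide
XP_011157711.1	OBP3	OBP	73	6.5	640	
ADX94399.1	OBP2	OBP	1.9	1.4	0	
ADX94401.1	OBP5	OBP	0.95	0.25	0	
ADX94412.1	OBP16	OBP	0.45	0	0.39	
ACI30688.1	OBP1	OBP	0.45	0.38	0	
ADX94403.1	OBP7	OBP	0.29	0.10	0.083	
ADX94407.1	OBP11	OBP	0.23	0	0	
ADX94410.1	OBP14	OBP	0.12	0.18	0	
ACI30690.1	OBP15	OBP	0.060	0	0.031	worker_tibia
ADX94402.1	OBP6	OBP	0.047	0	0	worker_antenna
ADX94400.1	OBP4	OBP	0	0	0.031	
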