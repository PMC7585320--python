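accession	name	family	worker_antenna	male_antenna	worker_tibia	single_peptide
XP_025990771.1	4C1	P450	2.3	0.40	0.42	
XP_011169811.1	4C1	P450	1.9	0.33	0.52	
XP_011164432.1	6a14	P450	0.85	0.33	0	
XP_025990773.1	4C1	P450	0.77	0.33	0.041	
XP_025995732.1	6a14	P450	0.71	0.25	0.088	
XP_025995731.1	6a14	P450	0.71	0	0.088	
XP_025986987.1	6k1	P450	0.32	0.037	0	
XP_025986982.1	6k1	P450	0.31	0.068	0	
XP_011162032.1	6k1	P450	0.30	0.065	0	
XP_011172133.1	6j1	P450	0.26	0.099	0.11	
XP_025986058.1	4C1	P450	0.23	0	0.026	
XP_025991592.1	4c21	P450	0.20	0	0	
XP_025986433.1	9e2	P450	0.15	0.049	0	
XP_011175444.1	9e2	P450	0.15	0.022	0	
XP_011158950.2	6k1	P450	0.12	0	0	
XP_011155385.1	9e2	P450	0.11	0.036	0.038	
XP_011172783.1	9e2	P450	0.075	0.063	0.085	
AAQ90477.1	4C1	P450	0.075	0.036	0	
XP_025986432.1	9e2	P450	0.075	0	0	
XP_011175440.1	9e2	P450	0.069	0.036	0	
XP_011158271.1	9e2	P450	0.069	0.036	0	
XP_025987661.1	6a1	P450	0.048	0.032	0	
XP_025988558.1	304a1	P450	0.037	0	0	worker_antenna
XP_011172178.1	6j1	P450	0.037	0	0	worker_antenna
XP_011164533.1	6k1	P450	0.037	0	0	worker_antenna
XP_025989949.1	4C1	P450	0.032	0	0	worker_antenna
XP_011167674.2	6a13	P450	-	-	0	male_antenna
XP_011172542.1	4C1	P450	-	0	0	
XP_025994582.1	6a20	P450	-	0	0	
XP_025992592.1	6a14	P450	0	0.13	0.11	
XP_011172813.1	9e2	P450	0	0.049	0	
XP_025996422.1	4C1	P450	0	0.026	0	
XP_011166535.1	9e2	P450	0	0.024	0	
XP_011160035.1	9e2	P450	0	0.012	0	male_antenna
XP_025993629.1	305a1	P450	0	0.012	0	male_antenna
AJW31562.1	4C1	P450	0	0	0.085	
XP_011164433.2	6a14	P450	0	0	0.062	
AJW31561.1	4G15	P450	0	0	0.059	
XP_025986515.1	4C1	P450	0	0	0.026	
XP_025986504.1	9e	P450	0	0	0.018	
XP_011164781.1	12A2	P450	0	0	0.018	worker_tibia
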