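mw_low_kda	mw_high_kda	dilution	accession	abundance
400	600	dilute	Orco	0.40
400	600	dilute	SNMP1	0.91
400	600	dilute	XP_011164432.1	1.4
400	600	dilute	XP_025986987.1	0.26
200	350	dilute	Orco	0.30
200	350	dilute	SNMP1	0.40
200	350	dilute	XP_011164432.1	0.29
200	350	dilute	XP_025986987.1	0.19
400	600	concentrated	Orco	0.51
400	600	concentrated	SNMP1	1.6
400	600	concentrated	XP_011164432.1	1.8
400	600	concentrated	XP_025986987.1	1.1
200	350	concentrated	Orco	0.44
200	350	concentrated	SNMP1	1.3
200	350	concentrated	XP_011164432.1	0.37
200	350	concentrated	XP_025986987.1	0.39
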