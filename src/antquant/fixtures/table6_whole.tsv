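accession	name	family	worker_antenna	male_antenna	single_peptide
Orco	Orco	ORCO	3.1	0.64	
SNMP1	SNMP1	SNMP	5.0	6.4	
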