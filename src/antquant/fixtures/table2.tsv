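accession	name	family	worker_antenna	male_antenna	worker_tibia	single_peptide
ACJ64059.1	CSP12	CSP	1.9	0.69	0.083	worker_tibia
XP_011160228.1	CSP16	CSP	1.9	0	0.23	
AAV91325.1	CSP19	CSP	1.2	1.8	0	
XP_011160273.1	CSP7	CSP	0.87	0	0	
ACJ64057.1	CSP9	CSP	0.45	0.69	0.083	
XP_011160926.1	CSP17	CSP	0.37	0	0.11	
XP_011168346.1	CSP18	CSP	0.35	0.85	0.18	
XP_011163783.1	CSP1	CSP	0.29	0.10	0	
AKP92835.1	CSP3	CSP	0.25	0.57	0.071	
XP_011160226.1	CSP11	CSP	0.13	1.1	0	
XP_011160224.1	CSP21	CSP	0.097	0	0.050	
AKP92833.1	CSP13	CSP	0	0.12	0	male_antenna
ACJ64056.1	CSP8	CSP	0	0	0.18	
XP_011160225.1	CSP15	CSP	0	0	0.11	
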