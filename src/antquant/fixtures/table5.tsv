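accession	name	family	worker_antenna	male_antenna	worker_tibia	single_peptide
XP_011165644.1	GST	GST	0.74	0.39	0.49	
XP_025993326.1	xanthine dehyd.	DEHYDROGENASE	0.63	0.38	0.017	
XP_025992003.1	GST	GST	0.57	0.45	0.055	
XP_025996377.1	GST 1-like	GST	0.55	0	0.069	
XP_011158662.1	GST 1	GST	0.29	0.63	0.21	
XP_011165884.1	xanthine dehyd. 1-like	DEHYDROGENASE	0.36	0.29	0.017	
XP_025989394.1	UDP-GT 2B31-like	UDPGT	0.40	0.15	0	
XP_011159399.1	retinol dehyd. 12	DEHYDROGENASE	0.25	0.53	0.10	
XP_011159136.1	GST theta-3 X1	GST	0.20	0.18	0.075	
ABA39530.1	GST	GST	1.8	0.98	0.94	
XP_025987486.1	UDP-GT1-9	UDPGT	0.25	0.063	0.062	
XP_025990737.1	UDP-GT 2B1-like X2	UDPGT	0.24	0.11	0	
XP_025987060.1	retinol dehyd. 12	DEHYDROGENASE	0.16	0	0	
XP_025995400.1	UDP-GT 2B20	UDPGT	0.20	0.031	0.024	worker_tibia
XP_011160692.1	esterase FE4 X2	ESTERASE	0.16	0.022	0	
XP_025995399.1	UDP-GT 2C1-like	UDPGT	0.14	0	0	worker_antenna
XP_025994825.1	JH esterase-like	ESTERASE	0.14	0	0.051	worker_tibia
XP_011165649.2	GST	GST	0.097	0	0	
XP_025991890.1	UDP-GT 2B31	UDPGT	0.11	0	0	
XP_011163179.1	esterase E4 X1	ESTERASE	0.11	0	0	
XP_011168182.1	GST 1 X2	GST	0.052	0.39	0	worker_antenna
XP_025989254.1	xanthine dehyd. X1	DEHYDROGENASE	0.0068	0.0043	0	worker_antenna
XP_011164602.1	esterase FE4-like	ESTERASE	0	0.10	0.018	worker_tibia
XP_011165643.1	GST-like	GST	0	0.15	0	
XP_011162023.1	carboxylesterase-6	ESTERASE	0	0.27	0.062	
XP_025990047.1	retinal dehyd. 1	DEHYDROGENASE	0	0	0.13	
XP_011165650.1	GST-like	GST	0	0	0.075	
XP_011162756.1	retinol dehyd. 11	DEHYDROGENASE	0	0	0.045	
XP_011168216.2	UDP-GT 2B31	UDPGT	0	0	0.038	
XP_011165649.2	GST	GST	0	0	0.024	worker_tibia
XP_011164603.1	retinol dehyd. 14	DEHYDROGENASE	0	0	0.022	worker_tibia
XP_011170697.1	retinol dehyd. 13	DEHYDROGENASE	0	0	0.022	worker_tibia
XP_011171057.1	UDP-GT 2B31	UDPGT	0	0	0.021	worker_tibia
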