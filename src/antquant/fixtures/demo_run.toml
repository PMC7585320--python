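# Demo configuration: a small synthetic experiment run end to end.

[run]
reference_accession = "GAPDH"
trypsin_accession = "TRYPSIN"
orco_accession = "ORCO"
snmp_accession = "SNMP1"
fdr_target = 0.01

[simulation]
n_proteins = 60
seed = 11
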