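file	n_rows	numeric_sum
table1.tsv	11	726.842
table2.tsv	14	14.824
table3.tsv	15	4.505
table4.tsv	41	14.21
table5.tsv	33	15.1431
table6_sections.tsv	16	12411.66
table6_whole.tsv	2	15.14
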