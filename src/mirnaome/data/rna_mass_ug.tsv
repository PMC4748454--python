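sample_number	sample_name	total_rna_ug
1	FA01A	0.0054
2	FA02A	0.0033
3	FA03A	0.0179
4	FA04A	0.0046
5	FA05A	0.0079
6	FA06A	0.0034
7	FA07A	0.0032
8	FA08A	0.0048
9	FA09A	0.0093
10	MA01A	0.0041
11	MA02A	0.0054
12	MA03A	0.0143
13	MA04A	0.0153
14	MA05A	0.0084
15	MA06A	0.0088
16	MA07A	0.0193
17	MA08A	0.0392
18	MA09A	0.0144
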