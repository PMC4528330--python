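pair	n_introns	junction_support	similar_alternative	within_coding	within_5utr	within_lncrna
AT-AC (U12)	9	9	1	9	0	0
AT-AC (U2)	4	4	2	4	0	0
GT-TG	23	19	22	13	9	1
GT-GG	6	5	5	3	2	1
GT-CG	8	8	8	6	2	0
GT-AT	14	11	14	11	3	0
GT-AA	3	3	3	2	1	0
GA-AG	12	12	5	8	3	1
GG-AG	0	0	0	0	0	0
GT-AC	0	0	0	0	0	0
GT-AG (U12)	10	9	0	9	1	0
GC-AG (U12)	1	1	0	1	0	0
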