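# Published per-miRNA clean-tag counts from the RSS vs. normal chicken liver
# small-RNA libraries, with the library-level clean-read totals.
# count_a = RSS library, count_b = normal library.
# up_in: library with the higher TPM as printed (a = RSS, b = normal).
# printed_p / printed_l2fc: values as printed (p truncated to "<0.0001" for
# strongly significant rows); kept for regression checks only.
#name_a=RSS
#name_b=normal
#total_a=9246256
#total_b=8714768
tag_id	count_a	count_b	up_in	printed_l2fc	printed_p
miR-196	4	24	b	2.67	<0.0001
miR-499	4	21	b	2.48	0.0003
miR-216b	5	24	b	2.35	0.0002
miR-1551	10	34	b	1.85	0.0001
miR-217	12	34	b	1.59	0.0005
miR-375	556	1249	b	1.25	<0.0001
miR-1682	21	40	b	1.02	0.0078
miR-30c	931	414	a	1.08	<0.0001
miR-221	1023	452	a	1.09	<0.0001
miR-2188	201	88	a	1.11	<0.0001
miR-30b	217	91	a	1.17	<0.0001
miR-215	1305	547	a	1.17	<0.0001
miR-1662	1534	636	a	1.18	<0.0001
miR-18b	25	10	a	1.24	0.01846
miR-3536	383	127	a	1.51	<0.0001
miR-23b	49	16	a	1.53	<0.0001
miR-3535	24	6	a	1.91	0.0015
miR-1744	42	9	a	2.14	<0.0001
miR-3524	11	2	a	2.37	0.0175
miR-367	12	0	a	7.02	0.0004
miR-302b	339	1	a	8.32	<0.0001
miR-302c	47	0	a	8.99	<0.0001
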