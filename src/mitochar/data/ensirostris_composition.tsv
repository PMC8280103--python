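# Published nucleotide composition and skew table for the Exhippolysmata
# ensirostris mitogenome (GenBank MK681888). Percentages as printed (2 dp),
# skews as printed (3 dp). The cox3 AT-skew value is carried verbatim from the
# published table although it is inconsistent with the printed A%/T% of the
# same row (recomputation gives -0.112); downstream checks use recomputed
# skews from the percentage columns.
Region	Size	A	T	G	C	AT	AT_skew	GC_skew
Mitogenome	16350	32.51	31.91	14.24	21.33	64.43	0.009	-0.199
nad4	1227	22.96	39.82	23.05	14.17	62.79	-0.269	0.239
nad4l	255	23.53	38.43	25.88	12.16	61.96	-0.240	0.361
nad6	498	27.91	36.55	12.65	22.89	64.46	-0.134	-0.288
cob	1137	26.47	35.09	15.92	22.52	61.57	-0.140	-0.172
nad1	870	22.76	40.34	23.33	13.56	63.10	-0.279	0.265
nad2	982	26.48	36.25	10.90	26.37	62.73	-0.156	-0.415
cox1	1512	26.32	33.80	17.99	21.89	60.12	-0.124	-0.098
cox2	687	31.00	32.61	15.87	20.52	63.61	-0.025	-0.128
atp8	165	34.55	41.82	4.85	18.79	76.36	-0.095	-0.590
atp6	666	26.43	36.04	12.91	24.62	62.46	-0.153	-0.312
cox3	783	26.82	33.59	17.50	22.09	60.41	0.975	-0.116
nad3	366	26.78	37.43	13.93	21.86	64.21	-0.166	-0.222
nad5	1704	25.23	38.32	22.77	13.67	63.56	-0.206	0.250
PCGs	10852	26.00	36.60	18.00	19.40	62.60	-0.169	-0.037
tRNAs	1446	32.92	32.13	18.74	15.21	66.04	0.012	0.104
rRNAs	2186	31.05	35.57	20.53	12.85	66.62	-0.068	0.230
CR	1249	35.23	34.09	14.14	16.53	69.33	0.016	-0.078
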