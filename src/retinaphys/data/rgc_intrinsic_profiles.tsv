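species	cell_id	vm	rn	tau	sag	steady_freq	max_freq	fa	amplitude	sw
bovine	GC1	-53	130	14.3	-8.78	27.9	149.3	0.81	107.8	0.86
bovine	GC2	-52	81	4.1	-2.97	54.6	166.7	0.67	91.4	0.80
bovine	GC3	-56	159	11.7	1.13	35.6	111.0	0.68	76.1	1.15
bovine	GC4	-58	324	17.4	-1.08	22.4	65.4	0.66	59.0	1.43
bovine	GC5	-55	49	44.1	1.75	43.2	80.9	0.47	47.7	1.01
bovine	GC6	-60	158	41.5	-5.24	18.2	52.7	0.65	89.5	1.17
bovine	GC7	-57	95	53.2	-7.99	51.4	176.5	0.71	103.5	0.54
bovine	GC8	-60	79	41.7	-7.44	59.0	168.7	0.65	103.3	0.57
bovine	GC9	-59	207	81.6	-6.53	49.9	114.5	0.56	89.6	0.99
bovine	GC10	-55	133	42.4	-7.24	45.5	130.3	0.65	90.4	0.72
mouse	GC1	-54	700	80.3	-12.19	30.2	75.7	0.60	61.0	2.02
mouse	GC2	-53	496	28.8	-6.30	26.5	80.8	0.67	97.8	1.37
mouse	GC3	-51	244	19.1	-6.98	48.6	135.5	0.64	78.2	0.94
mouse	GC4	-46	113	60.0	-3.71	52.4	137.0	0.62	87.4	1.08
mouse	GC5	-50	526	24.2	-4.67	25.8	80.0	0.68	68.3	1.56
mouse	GC6	-47	499	179.3	-7.33	58.8	110.0	0.47	46.2	1.18
mouse	GC7	-57	146	7.5	-4.43	107.2	210.4	0.49	86.6	0.94
mouse	GC8	-60	758	29.4	-6.18	41.7	98.4	0.58	63.6	1.05
mouse	GC9	-54	711	44.8	-7.59	45.1	98.9	0.54	82.4	1.66
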