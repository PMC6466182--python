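# Per-ORF crossover accounting for the recombinant genome, transcribed from
# the printed table (positions are 1-based recombinant coordinates; the
# genome starts and ends in parent-A material, total length 73,050 bp
# inferred from the terminal-repeat note).
orf_id	n_crossovers	crossover_positions
02	1	1020
03	1	1210
08	1	2581
10	1	2884
17	1	5352
18	1	5840
23	1	8764
23a	1	9384
35	1	16721
37	2	19203;19359
42	1	22811
43	5	25434;26071;26254;26321;26473
IG44-45	1	27137
45	1	27326
51	1	29758
52	6 (+1 missense)	30115;30122;31070;31073;31118;33095
53	2	33375;33379
59	2	38669;39095
66	1	43324
67	1	44210
70	1	54100
71	3	55210;55751;56313
72	1	56747
73	1	59203
75	1	60455
77	3	62768;63143;63333
79	1	64015
82	1	67134
83	3	68333;68417;68774
85	1	70398
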