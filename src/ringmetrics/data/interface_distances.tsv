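structure	interface	atp_site	h2i_ps1b	dna_melted
Class1a	D:E	8.713	16.351	no
Class1a	C:D	8.959	16.46	no
Class1a	B:C	9.043	16.19	no
Class1a	A:B	8.961	16.471	no
Class1a	F:A	8.828	16.305	no
Class1a	E:F	8.913	16.487	no
7W1Y	7:3	5.219	7.496	no
7W1Y	4:7	5.059	7.341	no
7W1Y	6:4	5.597	7.279	no
7W1Y	2:6	9.454	19.985	no
7W1Y	5:2	8.387	12.378	no
7W1Y	3:5	5.729	7.134	no
5BK4	7:3	7.049	8.594	no
5BK4	4:7	6.337	8.68	no
5BK4	6:4	6.695	7.691	no
5BK4	2:6	9.071	21.671	no
5BK4	5:2	10.281	12.446	no
5BK4	3:5	7.321	10.877	no
9GJW	7:3	7.414	7.166	no
9GJW	4:7	5.497	8.547	no
9GJW	6:4	5.176	7.684	no
9GJW	2:6	5.696	7.147	no
9GJW	5:2	7.368	15.688	no
9GJW	3:5	10.504	16.735	no
9E2X	7:3	9.086	13.195	na
9E2X	4:7	9.344	7.121	na
9E2X	6:4	7.015	6.746	na
9E2X	2:6	5.259	7.74	na
9E2X	5:2	6.712	14.124	na
9E2X	3:5	9.03	14.331	na
Class2a	D:E	8.339	13.956	2
Class2a	C:D	8.41	13.9	2
Class2a	B:C	7.598	12.423	2
Class2a	A:B	5.973	7.491	2
Class2a	F:A	5.63	7.662	2
Class2a	E:F	8.11	14.953	2
7PMN	7:3	7.744	11.603	2
7PMN	4:7	6.125	12.507	2
7PMN	6:4	7.244	7.126	2
7PMN	2:6	5.217	7.268	2
7PMN	5:2	5.219	7.235	2
7PMN	3:5	8.511	21.045	2
Class2b	D:E	8.483	15.448	4
Class2b	C:D	8.152	14.074	4
Class2b	B:C	8.325	12.656	4
Class2b	A:B	6.186	7.362	4
Class2b	F:A	5.502	7.479	4
Class2b	E:F	5.504	7.859	4
7PMK	7:3	8.365	16.895	4
7PMK	4:7	6.546	12.843	4
7PMK	6:4	6.987	11.214	4
7PMK	2:6	5.143	7.179	4
7PMK	5:2	5.121	6.967	4
7PMK	3:5	5.693	7.138	4
7Z13	7:3	8.488	14.821	>4
7Z13	4:7	7.964	12.973	>4
7Z13	6:4	9.244	13.964	>4
7Z13	2:6	6.733	7.426	>4
7Z13	5:2	5.861	7.455	>4
7Z13	3:5	5.848	7.533	>4
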