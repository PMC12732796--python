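ref_seq_index	ref_aa	generic_label	segment
100	S	1.40	TM1
101	P	1.41	TM1
102	W	1.42	TM1
103	Q	1.43	TM1
104	M	1.44	TM1
105	M	1.45	TM1
106	S	1.46	TM1
107	P	1.47	TM1
108	R	1.48	TM1
109	Y	1.49	TM1
110	A	1.50	TM1
111	K	1.51	TM1
112	I	1.52	TM1
113	D	1.53	TM1
114	F	1.54	TM1
115	I	1.55	TM1
150	W	2.37	TM2
151	W	2.38	TM2
152	Q	2.39	TM2
153	P	2.40	TM2
154	C	2.41	TM2
155	S	2.42	TM2
156	W	2.43	TM2
157	S	2.44	TM2
158	Q	2.45	TM2
159	V	2.46	TM2
160	I	2.47	TM2
161	L	2.48	TM2
162	S	2.49	TM2
163	D	2.50	TM2
164	H	2.51	TM2
165	A	2.52	TM2
205	F	3.41	TM3
206	D	3.42	TM3
207	Y	3.43	TM3
208	F	3.44	TM3
209	A	3.45	TM3
210	W	3.46	TM3
211	M	3.47	TM3
212	N	3.48	TM3
213	D	3.49	TM3
214	R	3.50	TM3
215	H	3.51	TM3
216	K	3.52	TM3
217	V	3.53	TM3
218	I	3.54	TM3
219	K	3.55	TM3
220	P	3.56	TM3
221	C	34.50	ICL2
222	L	34.51	ICL2
223	N	34.52	ICL2
224	K	34.53	ICL2
225	Q	34.54	ICL2
226	Y	34.55	ICL2
227	I	34.56	ICL2
228	Q	34.57	ICL2
230	E	4.40	TM4
231	S	4.41	TM4
232	D	4.42	TM4
233	D	4.43	TM4
234	N	4.44	TM4
235	I	4.45	TM4
236	N	4.46	TM4
237	A	4.47	TM4
238	N	4.48	TM4
239	K	4.49	TM4
240	N	4.50	TM4
241	S	4.51	TM4
242	R	4.52	TM4
243	H	4.53	TM4
244	F	4.54	TM4
245	P	4.55	TM4
288	A	5.57	TM5
289	L	5.58	TM5
290	T	5.59	TM5
291	R	5.60	TM5
292	Y	5.61	TM5
293	K	5.62	TM5
294	F	5.63	TM5
295	T	5.64	TM5
296	L	5.65	TM5
297	V	5.66	TM5
298	S	5.67	TM5
299	G	5.68	TM5
300	P	5.69	TM5
301	S	5.70	TM5
302	E	5.71	TM5
303	C	5.72	TM5
336	R	6.28	TM6
337	F	6.29	TM6
338	E	6.30	TM6
339	R	6.31	TM6
340	A	6.32	TM6
341	L	6.33	TM6
342	L	6.34	TM6
343	Q	6.35	TM6
344	S	6.36	TM6
345	C	6.37	TM6
346	S	6.38	TM6
347	F	6.39	TM6
348	K	6.40	TM6
349	G	6.41	TM6
350	P	6.42	TM6
351	P	6.43	TM6
385	G	7.41	TM7
386	D	7.42	TM7
387	S	7.43	TM7
388	Q	7.44	TM7
389	S	7.45	TM7
390	Q	7.46	TM7
391	R	7.47	TM7
392	Q	7.48	TM7
393	L	7.49	TM7
394	G	7.50	TM7
395	Y	7.51	TM7
396	Y	7.52	TM7
397	H	7.53	TM7
398	Q	7.54	TM7
399	G	7.55	TM7
400	N	7.56	TM7
401	Y	8.47	H8
402	T	8.48	H8
403	Q	8.49	H8
404	T	8.50	H8
405	R	8.51	H8
406	Y	8.52	H8
407	E	8.53	H8
408	S	8.54	H8
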