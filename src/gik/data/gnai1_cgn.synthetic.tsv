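ref_seq_index	ref_aa	generic_label	segment
320	T		
321	A		
322	I		
323	W		
324	K		
325	K		
326	T		
327	N		
328	P		
329	W	H5.01	H5
330	V	H5.02	H5
331	R	H5.03	H5
332	S	H5.04	H5
333	H	H5.05	H5
334	M	H5.06	H5
335	M	H5.07	H5
336	Q	H5.08	H5
337	V	H5.09	H5
338	G	H5.10	H5
339	R	H5.11	H5
340	F	H5.12	H5
341	C	H5.13	H5
342	D	H5.14	H5
343	K	H5.15	H5
344	D	H5.16	H5
345	G	H5.17	H5
346	Q	H5.18	H5
347	C	H5.19	H5
348	L	H5.20	H5
349	K	H5.21	H5
350	I	H5.22	H5
351	G	H5.23	H5
352	K	H5.24	H5
353	L	H5.25	H5
354	F	H5.26	H5
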