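ref_seq_index	ref_aa	generic_label	segment
360	G		
361	T		
362	H		
363	Y		
364	W		
365	I		
366	G		
367	E		
368	I		
369	S	H5.01	H5
370	Q	H5.02	H5
371	M	H5.03	H5
372	C	H5.04	H5
373	V	H5.05	H5
374	P	H5.06	H5
375	S	H5.07	H5
376	F	H5.08	H5
377	H	H5.09	H5
378	R	H5.10	H5
379	R	H5.11	H5
380	R	H5.12	H5
381	M	H5.13	H5
382	K	H5.14	H5
383	I	H5.15	H5
384	A	H5.16	H5
385	V	H5.17	H5
386	L	H5.18	H5
387	V	H5.19	H5
388	L	H5.20	H5
389	Y	H5.21	H5
390	G	H5.22	H5
391	Y	H5.23	H5
392	F	H5.24	H5
393	L	H5.25	H5
394	L	H5.26	H5
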