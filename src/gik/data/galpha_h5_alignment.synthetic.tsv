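	H5.01	H5.02	H5.03	H5.04	H5.05	H5.06	H5.07	H5.08	H5.09	H5.10	H5.11	H5.12	H5.13	H5.14	H5.15	H5.16	H5.17	H5.18	H5.19	H5.20	H5.21	H5.22	H5.23	H5.24	H5.25	H5.26
Gs	W	I	A	A	Y	S	K	C	I	W	L	H	Q	W	R	R	C	L	C	K	N	E	H	M	L	H
Gi1	W	E	A	C	R	K	K	C	M	L	H	M	Q	F	E	A	I	I	N	K	I	P	L	Y	L	R
Gi2	W	S	A	W	E	I	K	C	W	Q	V	F	Q	C	S	F	H	F	Y	K	N	W	E	P	L	P
Gq	W	R	A	H	V	W	K	C	D	V	L	C	Q	T	T	R	Y	W	Q	K	C	M	K	Y	L	W
G12	W	T	A	E	L	W	K	C	E	M	G	Q	Q	Y	S	G	W	G	G	K	L	N	D	N	L	S
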