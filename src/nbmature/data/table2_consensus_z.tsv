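# Transcription of the published 'top 50 consensus Z-scores (<0)'
# single-mutant table. The parent clone's own consensus Z is -0.20.
# Data, not computed output.
position	wt	mut	z
55	S	D	-2.2
55	S	F	-1.8
55	S	L	-2.1
55	S	N	-1.7
55	S	Q	-2.3
55	S	R	-2.7
55	S	Y	-1.7
58	V	D	-2.1
58	V	K	-1.7
58	V	L	-1.9
58	V	M	-1.7
58	V	N	-1.7
58	V	S	-1.7
58	V	T	-1.7
107	G	E	-1.8
107	G	F	-1.7
107	G	H	-1.7
107	G	I	-2.2
107	G	K	-1.8
107	G	L	-1.8
107	G	M	-1.8
107	G	Q	-1.9
107	G	R	-2.1
107	G	S	-1.9
107	G	T	-2.1
107	G	V	-1.7
107	G	W	-2.0
107	G	Y	-1.9
108	T	F	-1.7
108	T	H	-2.3
108	T	K	-2.1
108	T	V	-1.7
108	T	W	-1.9
108	T	Y	-1.8
109	S	D	-2.0
109	S	E	-2.3
109	S	F	-1.9
109	S	G	-2.0
109	S	K	-1.6
109	S	N	-1.6
109	S	V	-2.0
109	S	W	-1.7
110	F	A	-2.0
110	F	E	-1.6
110	F	L	-1.7
110	F	N	-2.0
110	F	Q	-1.7
110	F	R	-2.2
110	F	S	-1.9
110	F	V	-1.6
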