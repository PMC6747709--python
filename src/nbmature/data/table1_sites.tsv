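# Transcription of a published two-criteria binding-site analysis for an
# anti-CD47 VHH (interface residues within 5 A of the antigen; AGY/RGYW
# hotspot residues on the coding DNA). Data, not computed output.
criterion	residues	aa
interface	32	E
interface	35	Q
interface	36	N
interface	54	I
interface	55	S
interface	57	R
interface	58	V
interface	60	E
interface	61	C
interface	62	W
interface	105-113	-
hotspot	34	S
hotspot	55	S
hotspot	56	S
hotspot	58	V
hotspot	59	V
hotspot	100	A
hotspot	101	A
hotspot	107	G
hotspot	108	T
hotspot	109	S
hotspot	110	F
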