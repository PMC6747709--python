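# Transcription of published SPR K_D (1:1 Langmuir fits) and thermal-shift
# T_M values for the parent anti-CD47 VHH (M0) and seven multi-point
# mutants. Mutation composition is published only for M7.
# Data, not computed output.
mutant	label	kd_nM	kd_err_nM	tm_C
M0	WT	278	9.3	43.38
M1	-	74.5	5.5	57.47
M2	-	11.4	2.1	60.59
M3	-	69.5	6.1	60.01
M4	-	57.0	7.3	43.08
M5	-	25.3	3.7	51.16
M6	-	58.2	4.5	48.91
M7	G107W+T108H+S109V+F110A	3.18	1.0	50.74
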