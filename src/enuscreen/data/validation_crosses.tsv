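name	parent1_f5	parent1_tfpi	parent1_mod	parent2_f5	parent2_tfpi	parent2_mod	n_total	rescues_with	rescues_without
Arl6ip5	L/L	+/+	+/m	L/+	+/-	+/+	205	5	1
Itgb6	L/L	+/+	+/m	L/+	+/-	+/+	154	1	1
C6	L/L	+/+	+/m	L/+	+/-	+/+	106	0	0
Cpn1	L/L	+/+	+/m	L/+	+/-	+/+	139	1	0
Sntg1	L/L	+/+	+/m	L/+	+/-	+/+	223	4	3
Ces3b	L/L	+/+	+/m	L/+	+/-	+/+	219	1	2
Plcb4_ins1	L/L	+/+	+/ins1	L/+	+/-	+/+	169	10	1
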