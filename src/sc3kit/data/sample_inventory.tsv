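embryo_id	sex	stage	picked_from	cdna_constructed	good_quality	sc3seqed
130206ICSI#1day6	male	E06	whole embryo	47	45	23
130227ICSI#1day6	female	E06	whole embryo	47	42	18
130306ICSI#7day6	female	E06	whole embryo	39	26	2
121128ICSI#1day7	male	E07	whole embryo	47	32	10
121205ICSI#1day7	male	E07	whole embryo	47	35	17
130319ICSI#1day7	male	E07	whole embryo	23	15	8
121107ICSI13_day8	male	E08	whole embryo	59	53	36
121212ICSI#11day8	male	E08	whole embryo	47	38	21
130220ICSI#11day8	male	E08	whole embryo	47	47	38
120725ICSIday9	male	E09	whole embryo	58	45	12
121212ICSI#2day9	female	E09	whole embryo	47	37	8
140812ICSId13A	male	E13	around embryonic disk	60	58	49
140401ICSIday14	male	E14	around embryonic disk	48	43	33
141014ICSIday14A	male	E14	around embryonic disk	60	58	30
140401ICSIday16	male	E16	around embryonic disk	48	46	36
140708ICSIday16	female	E16	posterior third of embryonic disk	96	94	8
140701ICSIday17	female	E17	around body stalk	96	92	3
140722ICSIday17A	male	E17	around embryonic disk	96	94	55
140401ICSIday20	male	E20	around body stalk	96	79	8
140708ICSId36#60	male	E36	genital ridge	48	13	6
130522ICSI-PGCday43	female	E43	genital ridge	58	55	7
130522ICSI-PGCday47	male	E47	genital ridge	60	34	1
130523ICSI-PGCAday50	female	E50	genital ridge	60	9	5
130522ICSI-PGCday51	female	E51	genital ridge	60	47	7
130522ICSI-PGCAday55	male	E55	genital ridge	30	17	1
130522ICSI-PGCBday55	male	E55	genital ridge	30	16	1
CMK9	female	p25	on feeder	24	9	3
CMK9	female	p30	on feeder	21	14	5
CMK6	male	p32	on feeder	46	32	10
CMK6	male	p33	on feeder	24	13	4
CMK6	male	p35	off feeder	24	3	9
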