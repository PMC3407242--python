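population	code	origin	animals	FLN	LUN	MER	APD	APM	CAS	CHU	MEL	MIL	OJA	RAM	RAS	SUM	TIB
Florida Native	FLN	SE	40	0	6.2	5.4	10.3	5.3	5.2	6.5	5.4	6.1	4.8	6.9	4.0	14.5	11.0
Louisiana Native	LUN	SE	54	0.8	0	7.5	12.4	7.4	7.3	8.8	7.5	8.3	7.0	9.0	6.1	16.9	13.2
Merino	MER	SE	88	0.7	1.0	0	11.4	1.0	4.0	5.4	4.5	5.2	3.7	5.3	2.7	14.4	11.1
Poll Dorset	APD	NE	108	1.3	1.6	1.5	0	11.2	11.1	12.4	11.1	12.0	10.7	13.0	10.0	20.6	16.9
Poll Merino	APM	SE	98	0.7	1.0	0.3	1.5	0	3.9	5.3	4.4	5.1	3.6	5.0	2.6	14.1	10.9
Castellana	CAS	SE	23	0.7	0.9	0.5	1.4	0.6	0	4.5	4.0	4.7	2.9	5.9	2.1	13.7	10.4
Churra	CHU	SE	120	1.0	1.1	0.7	1.6	0.8	0.7	0	5.3	6.0	4.0	7.2	3.5	15.3	12.0
Meat Lacaune	MEL	CE	78	0.7	0.9	0.6	1.4	0.6	0.6	0.8	0	2.3	3.7	6.4	2.7	14.5	11.2
Milk Lacaune	MIL	CE	103	0.7	1.0	0.6	1.5	0.7	0.6	0.9	0.3	0	4.4	7.1	3.3	15.2	11.8
Ojalada	OJA	SE	24	0.7	1.0	0.6	1.4	0.6	0.5	0.6	0.6	0.6	0	5.5	1.8	13.6	10.3
Rambouillet	RAM	SE	102	1.0	1.3	0.9	1.7	0.7	1.1	1.1	1.0	1.1	1.0	0	4.4	16.4	13.2
Rasa Aragonesa	RAS	SE	22	0.6	0.9	0.5	1.4	0.5	0.4	0.6	0.4	0.5	0.4	0.9	0	12.7	9.5
Sumatra	SUM	A	24	1.6	1.7	1.6	2.1	1.6	1.6	1.7	1.6	1.6	1.6	1.8	1.5	0	13.2
Tibetan	TIB	A	37	1.2	1.4	1.3	1.9	1.3	1.3	1.4	1.3	1.3	1.3	1.6	1.2	1.6	0
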