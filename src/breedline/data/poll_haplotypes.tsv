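population	n_animals	n_haplotypes	H1	H2	H3	Other
Poll Merino	98	6	0.57	0.24	0.12	0.07
Merino	88	5	0.09	0.58	0.13	0.20
Florida Native	35	6	0.49	0.03	0.39	0.09
Louisiana Native	54	3	0.19	0.00	0.57	0.24
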