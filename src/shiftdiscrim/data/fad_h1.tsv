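position	nucleus	candidate	method	delta_exp	delta_calc	rs_printed
2	H1	O	B3PW91/DGDZVP	7.11	6.97	0.14
2	H1	S	B3PW91/DGDZVP	7.11	6.83	0.28
2	H1	N	B3PW91/DGDZVP	7.11	6.83	0.28
2	H1	O	B3LYP/6-31+G(d,p)	7.11	7.19	0.08
2	H1	S	B3LYP/6-31+G(d,p)	7.11	6.61	0.5
2	H1	N	B3LYP/6-31+G(d,p)	7.11	6.78	0.33
5	H1	O	B3PW91/DGDZVP	6.78	6.37	0.41
5	H1	S	B3PW91/DGDZVP	6.78	7.16	0.38
5	H1	N	B3PW91/DGDZVP	6.78	7.17	0.39
5	H1	O	B3LYP/6-31+G(d,p)	6.78	6.51	0.27
5	H1	S	B3LYP/6-31+G(d,p)	6.78	7.17	0.39
5	H1	N	B3LYP/6-31+G(d,p)	6.78	7.08	0.3
6	H1	O	B3PW91/DGDZVP	7.01	6.96	0.05
6	H1	S	B3PW91/DGDZVP	7.01	7.59	0.58
6	H1	N	B3PW91/DGDZVP	7.01	7.71	0.7
6	H1	O	B3LYP/6-31+G(d,p)	7.01	6.78	0.23
6	H1	S	B3LYP/6-31+G(d,p)	7.01	7.65	0.64
6	H1	N	B3LYP/6-31+G(d,p)	7.01	7.79	0.78
7	H1	O	B3PW91/DGDZVP	7.43	7.66	0.23
7	H1	S	B3PW91/DGDZVP	7.43	7.63	0.2
7	H1	N	B3PW91/DGDZVP	7.43	7.9	0.47
7	H1	O	B3LYP/6-31+G(d,p)	7.43	7.88	0.45
7	H1	S	B3LYP/6-31+G(d,p)	7.43	7.79	0.36
7	H1	N	B3LYP/6-31+G(d,p)	7.43	7.89	0.46
8	H1	O	B3PW91/DGDZVP	6.45	5.81	0.64
8	H1	S	B3PW91/DGDZVP	6.45	6.42	0.03
8	H1	N	B3PW91/DGDZVP	6.45	6.62	0.17
8	H1	O	B3LYP/6-31+G(d,p)	6.45	6.33	0.12
8	H1	S	B3LYP/6-31+G(d,p)	6.45	6.71	0.26
8	H1	N	B3LYP/6-31+G(d,p)	6.45	7.43	0.98
2′	H1	O	B3PW91/DGDZVP	7.22	7.28	0.06
2′	H1	S	B3PW91/DGDZVP	7.22	7.12	0.1
2′	H1	N	B3PW91/DGDZVP	7.22	7.8	0.58
2′	H1	O	B3LYP/6-31+G(d,p)	7.22	7.28	0.06
2′	H1	S	B3LYP/6-31+G(d,p)	7.22	7.04	0.18
2′	H1	N	B3LYP/6-31+G(d,p)	7.22	7.81	0.59
3′	H1	O	B3PW91/DGDZVP	6.77	7.15	0.38
3′	H1	S	B3PW91/DGDZVP	6.77	6.43	0.34
3′	H1	N	B3PW91/DGDZVP	6.77	7.23	0.46
3′	H1	O	B3LYP/6-31+G(d,p)	6.77	7.08	0.31
3′	H1	S	B3LYP/6-31+G(d,p)	6.77	6.47	0.3
3′	H1	N	B3LYP/6-31+G(d,p)	6.77	7.24	0.47
5′	H1	O	B3PW91/DGDZVP	6.77	6.57	0.2
5′	H1	S	B3PW91/DGDZVP	6.77	7.21	0.44
5′	H1	N	B3PW91/DGDZVP	6.77	6.51	0.26
5′	H1	O	B3LYP/6-31+G(d,p)	6.77	6.47	0.3
5′	H1	S	B3LYP/6-31+G(d,p)	6.77	7.17	0.4
5′	H1	N	B3LYP/6-31+G(d,p)	6.77	6.52	0.25
6′	H1	O	B3PW91/DGDZVP	7.22	7.84	0.62
6′	H1	S	B3PW91/DGDZVP	7.22	7.88	0.66
6′	H1	N	B3PW91/DGDZVP	7.22	7.19	0.03
6′	H1	O	B3LYP/6-31+G(d,p)	7.22	7.51	0.29
6′	H1	S	B3LYP/6-31+G(d,p)	7.22	8.2	0.98
6′	H1	N	B3LYP/6-31+G(d,p)	7.22	7.09	0.13
7′	H1	O	B3PW91/DGDZVP	4.72	4.84	0.12
7′	H1	S	B3PW91/DGDZVP	4.72	4.52	0.2
7′	H1	N	B3PW91/DGDZVP	4.72	4.56	0.16
7′	H1	O	B3LYP/6-31+G(d,p)	4.72	5.15	0.43
7′	H1	S	B3LYP/6-31+G(d,p)	4.72	5.03	0.31
7′	H1	N	B3LYP/6-31+G(d,p)	4.72	4.61	0.11
8′a	H1	O	B3PW91/DGDZVP	3.53	4.46	0.93
8′a	H1	S	B3PW91/DGDZVP	3.53	2.38	1.15
8′a	H1	N	B3PW91/DGDZVP	3.53	2.67	0.86
8′a	H1	O	B3LYP/6-31+G(d,p)	3.53	3.99	0.46
8′a	H1	S	B3LYP/6-31+G(d,p)	3.53	2.4	1.13
8′a	H1	N	B3LYP/6-31+G(d,p)	3.53	2.7	0.83
8′b	H1	O	B3PW91/DGDZVP	3.42	4.33	0.91
8′b	H1	S	B3PW91/DGDZVP	3.42	3.73	0.31
8′b	H1	N	B3PW91/DGDZVP	3.42	3.94	0.52
8′b	H1	O	B3LYP/6-31+G(d,p)	3.42	4.11	0.69
8′b	H1	S	B3LYP/6-31+G(d,p)	3.42	3.43	0.01
8′b	H1	N	B3LYP/6-31+G(d,p)	3.42	3.61	0.19
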