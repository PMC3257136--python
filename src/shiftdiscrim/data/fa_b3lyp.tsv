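position	nucleus	candidate	method	delta_exp	delta_calc	rs_printed
1	C13	FA	B3LYP/6-31+G(d,p)	127.8	126.1	1.6
2	C13	FA	B3LYP/6-31+G(d,p)	111.6	113.5	1.8
3	C13	FA	B3LYP/6-31+G(d,p)	151.5	145.1	6.4
4	C13	FA	B3LYP/6-31+G(d,p)	149.9	145.7	4.2
5	C13	FA	B3LYP/6-31+G(d,p)	116.5	111.4	5.1
6	C13	FA	B3LYP/6-31+G(d,p)	123.9	113.6	10.4
C-α	C13	FA	B3LYP/6-31+G(d,p)	115.9	107.7	8.2
C-β	C13	FA	B3LYP/6-31+G(d,p)	146.9	147.2	0.3
C=O	C13	FA	B3LYP/6-31+G(d,p)	171.2	162.7	8.5
OMe-3	C13	FA	B3LYP/6-31+G(d,p)	56.5	53.9	2.5
2	H1	FA	B3LYP/6-31+G(d,p)	7.2	6.7	0.5
5	H1	FA	B3LYP/6-31+G(d,p)	6.8	6.6	0.2
6	H1	FA	B3LYP/6-31+G(d,p)	7.5	7.9	0.4
C-α	H1	FA	B3LYP/6-31+G(d,p)	6.3	6.5	0.2
C-β	H1	FA	B3LYP/6-31+G(d,p)	7.6	7.8	0.2
OMe-3	H1	FA	B3LYP/6-31+G(d,p)	3.9	3.8	0.1
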