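position	nucleus	candidate	method	delta_exp	delta_calc	rs_printed
1	C13	O	B3PW91/DGDZVP	128.2	131.6	3.4
1	C13	S	B3PW91/DGDZVP	128.2	129.8	1.6
1	C13	N	B3PW91/DGDZVP	128.2	131.0	2.8
1	C13	O	B3LYP/6-31+G(d,p)	128.2	125.7	2.5
1	C13	S	B3LYP/6-31+G(d,p)	128.2	124.2	4.0
1	C13	N	B3LYP/6-31+G(d,p)	128.2	126.8	1.4
2	C13	O	B3PW91/DGDZVP	111.0	113.4	2.3
2	C13	S	B3PW91/DGDZVP	111.0	121.0	10.0
2	C13	N	B3PW91/DGDZVP	111.0	120.3	9.3
2	C13	O	B3LYP/6-31+G(d,p)	111.0	101.9	9.0
2	C13	S	B3LYP/6-31+G(d,p)	111.0	112.1	1.1
2	C13	N	B3LYP/6-31+G(d,p)	111.0	110.7	0.3
3	C13	O	B3PW91/DGDZVP	149.3	153.5	4.2
3	C13	S	B3PW91/DGDZVP	149.3	150.2	0.8
3	C13	N	B3PW91/DGDZVP	149.3	150.2	0.9
3	C13	O	B3LYP/6-31+G(d,p)	149.3	145.9	3.4
3	C13	S	B3LYP/6-31+G(d,p)	149.3	142.5	6.9
3	C13	N	B3LYP/6-31+G(d,p)	149.3	142.8	6.4
4	C13	O	B3PW91/DGDZVP	149.8	154.4	4.6
4	C13	S	B3PW91/DGDZVP	149.8	154.7	4.9
4	C13	N	B3PW91/DGDZVP	149.8	153.7	3.9
4	C13	O	B3LYP/6-31+G(d,p)	149.8	146.9	2.9
4	C13	S	B3LYP/6-31+G(d,p)	149.8	147.5	2.3
4	C13	N	B3LYP/6-31+G(d,p)	149.8	144.6	5.2
5	C13	O	B3PW91/DGDZVP	116.4	118.3	1.9
5	C13	S	B3PW91/DGDZVP	116.4	120.9	4.5
5	C13	N	B3PW91/DGDZVP	116.4	120.6	4.2
5	C13	O	B3LYP/6-31+G(d,p)	116.4	110.2	6.2
5	C13	S	B3LYP/6-31+G(d,p)	116.4	113.2	3.2
5	C13	N	B3LYP/6-31+G(d,p)	116.4	111.9	4.5
6	C13	O	B3PW91/DGDZVP	123.3	133.2	9.9
6	C13	S	B3PW91/DGDZVP	123.3	126.6	3.3
6	C13	N	B3PW91/DGDZVP	123.3	125.9	2.6
6	C13	O	B3LYP/6-31+G(d,p)	123.3	124.4	1.1
6	C13	S	B3LYP/6-31+G(d,p)	123.3	115.3	8.0
6	C13	N	B3LYP/6-31+G(d,p)	123.3	115.2	8.1
7	C13	O	B3PW91/DGDZVP	142.3	155.2	12.9
7	C13	S	B3PW91/DGDZVP	142.3	148.5	6.2
7	C13	N	B3PW91/DGDZVP	142.3	152.7	10.4
7	C13	O	B3LYP/6-31+G(d,p)	142.3	143.5	1.2
7	C13	S	B3LYP/6-31+G(d,p)	142.3	137.5	4.8
7	C13	N	B3LYP/6-31+G(d,p)	142.3	141.8	0.5
8	C13	O	B3PW91/DGDZVP	118.6	117.0	1.6
8	C13	S	B3PW91/DGDZVP	118.6	125.3	6.7
8	C13	N	B3PW91/DGDZVP	118.6	115.4	3.2
8	C13	O	B3LYP/6-31+G(d,p)	118.6	108.0	10.6
8	C13	S	B3LYP/6-31+G(d,p)	118.6	114.4	4.2
8	C13	N	B3LYP/6-31+G(d,p)	118.6	110.9	7.6
9	C13	O	B3PW91/DGDZVP	169.5	174.2	4.7
9	C13	S	B3PW91/DGDZVP	169.5	200.1	30.6
9	C13	N	B3PW91/DGDZVP	169.5	171.4	1.9
9	C13	O	B3LYP/6-31+G(d,p)	169.5	163.6	5.9
9	C13	S	B3LYP/6-31+G(d,p)	169.5	192.5	23.0
9	C13	N	B3LYP/6-31+G(d,p)	169.5	162.3	7.2
1′	C13	O	B3PW91/DGDZVP	134.7	138.7	4.0
1′	C13	S	B3PW91/DGDZVP	134.7	140.7	6.0
1′	C13	N	B3PW91/DGDZVP	134.7	139.4	4.7
1′	C13	O	B3LYP/6-31+G(d,p)	134.7	129.2	5.5
1′	C13	S	B3LYP/6-31+G(d,p)	134.7	135.2	0.5
1′	C13	N	B3LYP/6-31+G(d,p)	134.7	133.3	1.4
2′	C13	O	B3PW91/DGDZVP	128.5	133.6	5.1
2′	C13	S	B3PW91/DGDZVP	128.5	136.0	7.5
2′	C13	N	B3PW91/DGDZVP	128.5	132.9	4.4
2′	C13	O	B3LYP/6-31+G(d,p)	128.5	125.8	2.7
2′	C13	S	B3LYP/6-31+G(d,p)	128.5	123.6	4.9
2′	C13	N	B3LYP/6-31+G(d,p)	128.5	124.1	4.4
3′	C13	O	B3PW91/DGDZVP	116.1	120.3	4.2
3′	C13	S	B3PW91/DGDZVP	116.1	115.7	0.4
3′	C13	N	B3PW91/DGDZVP	116.1	121.8	5.7
3′	C13	O	B3LYP/6-31+G(d,p)	116.1	110.9	5.1
3′	C13	S	B3LYP/6-31+G(d,p)	116.1	108.4	7.7
3′	C13	N	B3LYP/6-31+G(d,p)	116.1	113.0	3.1
4′	C13	O	B3PW91/DGDZVP	158.1	160.3	2.3
4′	C13	S	B3PW91/DGDZVP	158.1	161.6	3.4
4′	C13	N	B3PW91/DGDZVP	158.1	161.9	3.8
4′	C13	O	B3LYP/6-31+G(d,p)	158.1	153.4	4.7
4′	C13	S	B3LYP/6-31+G(d,p)	158.1	152.6	5.5
4′	C13	N	B3LYP/6-31+G(d,p)	158.1	153.7	4.4
5′	C13	O	B3PW91/DGDZVP	116.1	116.6	0.5
5′	C13	S	B3PW91/DGDZVP	116.1	121.6	5.5
5′	C13	N	B3PW91/DGDZVP	116.1	116.7	0.6
5′	C13	O	B3LYP/6-31+G(d,p)	116.1	108.9	7.2
5′	C13	S	B3LYP/6-31+G(d,p)	116.1	111.8	4.3
5′	C13	N	B3LYP/6-31+G(d,p)	116.1	109.7	6.4
6′	C13	O	B3PW91/DGDZVP	128.5	133.4	4.9
6′	C13	S	B3PW91/DGDZVP	128.5	134.6	6.1
6′	C13	N	B3PW91/DGDZVP	128.5	135.2	6.7
6′	C13	O	B3LYP/6-31+G(d,p)	128.5	125.0	3.5
6′	C13	S	B3LYP/6-31+G(d,p)	128.5	125.8	2.8
6′	C13	N	B3LYP/6-31+G(d,p)	128.5	123.6	4.9
7′	C13	O	B3PW91/DGDZVP	73.4	75.1	1.7
7′	C13	S	B3PW91/DGDZVP	73.4	78.6	5.2
7′	C13	N	B3PW91/DGDZVP	73.4	79.4	5.9
7′	C13	O	B3LYP/6-31+G(d,p)	73.4	76.2	2.8
7′	C13	S	B3LYP/6-31+G(d,p)	73.4	81.7	8.3
7′	C13	N	B3LYP/6-31+G(d,p)	73.4	81.9	8.6
8′	C13	O	B3PW91/DGDZVP	48.3	75.3	26.9
8′	C13	S	B3PW91/DGDZVP	48.3	47.9	0.3
8′	C13	N	B3PW91/DGDZVP	48.3	55.5	7.2
8′	C13	O	B3LYP/6-31+G(d,p)	48.3	74.8	26.5
8′	C13	S	B3LYP/6-31+G(d,p)	48.3	50.6	2.3
8′	C13	N	B3LYP/6-31+G(d,p)	48.3	53.5	5.2
OMe	C13	O	B3PW91/DGDZVP	56.4	60.3	3.9
OMe	C13	S	B3PW91/DGDZVP	56.4	60.7	4.3
OMe	C13	N	B3PW91/DGDZVP	56.4	60.5	4.1
OMe	C13	O	B3LYP/6-31+G(d,p)	56.4	53.9	2.51
OMe	C13	S	B3LYP/6-31+G(d,p)	56.4	54.4	2.0
OMe	C13	N	B3LYP/6-31+G(d,p)	56.4	54.0	2.4
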