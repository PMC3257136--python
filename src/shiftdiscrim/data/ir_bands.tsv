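mode_label	experimental	O@B3LYP/6-31G(d,p)	S@B3LYP/6-31G(d,p)	N@B3LYP/6-31G(d,p)	O@B3LYP/6-31+G(d,p)	S@B3LYP/6-31+G(d,p)	N@B3LYP/6-31+G(d,p)
υ (O-H aliphatic)	3370	3782	3808	3810	3806	3633	3825
υ (O-H aromatic)	3370	3818	3760	3763	3822	3765	3612
υ (N-H)	3370			3612			3612
υ (O-H aromatic) [2]	3370	3822	3822	3822	3828	3828	3770
υa (CH2) + υs (C-H sp2)		3128	3156	3127	3130	3137	3114
υs (CH2) + υs (C-H sp3) + υs (C-H sp2)		3077	3089	3076	3081	3098	3094
υa (CH3) + υ (C-H sp2)		3154	3157	3155	3157	3159	3157
υ (C-H sp2) + υa (C-H sp2 aromatic)		3207	3204	3206	3207	3206	3201
υs (CH3)		3016	3026	3025	3017	3029	3027
υ (C-H sp3) + υs (CH2)	2930	3038	3018	2985	3073	3075	3064
δa (C-H sp2 aromatic) + υs (C-O)		1675	1673	1673	1664	1662	1662
υ (C=O) + υ (C=C trans) + δ(C-H) [+δ(N-H)]	1680	1794	1755	1758	1768	1701	1727
υs (C=C trans) + υ (C=O) + δ (C-H sp2) [+δ(N-H)]	1600	1691	1755	1685	1679	1754	1674
δa (CH3)	1510	1505	1502	1502	1509	1509	1510
δs (C-H sp2 aromatic) + υ (C-O secondary alcohol)	1480	1307	1307	1309	1311	1309	1308
δs (C-H sp2) + υ (C-O secondary alcohol)	1390	1319	1316	1319	1319	1327	1318
δs (C-H sp2) + δa (CH3)	1110	1225	1220	1179	1220	1228	1227
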