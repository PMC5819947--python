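case	side	pair	in_stn	exclusion_reason
1	L	01	1	
1	L	12	1	
1	L	23	1	
1	R	01	0	outside
1	R	12	0	outside
1	R	23	0	outside
2	L	01	1	
2	L	12	1	
2	L	23	0	dorso_lateral
2	R	01	1	
2	R	12	1	
2	R	23	0	dorso_lateral
3	L	01	1	
3	L	12	1	
3	L	23	1	
3	R	01	1	
3	R	12	1	
3	R	23	1	
4	L	01	1	
4	L	12	1	
4	L	23	1	
4	R	01	1	
4	R	12	1	
4	R	23	1	
5	L	01	1	
5	L	12	1	
5	L	23	1	
5	R	01	1	
5	R	12	1	
5	R	23	1	
6	L	01	0	below_border
6	L	12	1	
6	L	23	1	
6	R	01	1	
6	R	12	1	
6	R	23	1	
7	L	01	1	
7	L	12	1	
7	L	23	1	
7	R	01	1	
7	R	12	1	
7	R	23	1	
8	L	01	1	
8	L	12	1	
8	L	23	0	dorso_lateral
8	R	01	1	
8	R	12	1	
8	R	23	0	dorso_lateral
9	L	01	1	
9	L	12	1	
9	L	23	0	dorso_lateral
9	R	01	1	
9	R	12	1	
9	R	23	0	dorso_lateral
11	L	01	1	
11	L	12	1	
11	L	23	1	
11	R	01	1	
11	R	12	1	
11	R	23	1	
12	L	01	1	
12	L	12	1	
12	L	23	1	
12	R	01	1	
12	R	12	1	
12	R	23	1	
13	L	01	1	
13	L	12	1	
13	L	23	0	dorso_lateral
13	R	01	1	
13	R	12	1	
13	R	23	0	dorso_lateral
14	L	01	1	
14	L	12	0	dorso_lateral
14	L	23	0	dorso_lateral
14	R	01	1	
14	R	12	1	
14	R	23	0	dorso_lateral
15	L	01	1	
15	L	12	1	
15	L	23	1	
15	R	01	1	
15	R	12	1	
15	R	23	1	
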