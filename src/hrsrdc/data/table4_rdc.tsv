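id	atom1	atom2	isotope1	isotope2	r0_nm	set	d0_hz	mdsol_hz	hrsr_hz	at0_hz	at0p1_hz	at1_hz	at10_hz	atremvac_hz
1	H(2)	N(2)	1H	15N	0.100	1	3.4	3.5	3.7	2.7	2.7	0.7	0.0	2.3
2	H(3)	N(3)	1H	15N	0.100	1	5.6	5.3	5.3	3.2	3.3	0.6	-0.1	4.0
3	H(4)	N(4)	1H	15N	0.100	1	4.4	4.5	4.8	3.4	3.4	0.5	-0.1	3.0
4	H(5)	N(5)	1H	15N	0.100	1	4.5	4.3	4.5	2.5	2.6	1.0	0.0	3.0
5	H(6)	N(6)	1H	15N	0.100	1	5.2	4.9	5.0	2.9	2.9	0.1	-0.2	3.8
6	H(7)	N(7)	1H	15N	0.100	1	4.7	4.6	4.1	2.3	2.1	0.2	-0.1	3.4
7	HB(1)	CB(1)	1H	13C	0.109	2	-6.9	-6.5	-6.5	-4.2	-3.9	-1.6	-0.4	-6.2
8	HB(2)	CB(2)	1H	13C	0.109	2	-12.3	-12.3	-12.2	-8.1	-8.2	-2.5	-0.3	-9.6
9	HB(3)	CB(3)	1H	13C	0.109	2	-17.1	-15.3	-15.4	-9.2	-9.5	-2.6	-0.4	-11.7
10	HB(4)	CB(4)	1H	13C	0.109	2	-12.0	-12.1	-11.9	-8.9	-9.0	-1.7	-0.0	-10.2
11	HB(5)	CB(5)	1H	13C	0.109	2	-11.3	-11.1	-11.2	-7.9	-8.0	-3.2	-0.4	-10.0
12	HB(6)	CB(6)	1H	13C	0.109	2	-12.6	-12.1	-12.6	-8.6	-8.7	-1.6	-0.1	-9.9
13	HB(7)	CB(7)	1H	13C	0.109	2	-12.8	-11.7	-12.0	-6.3	-5.9	-1.2	-0.3	-9.5
14	HARe(1)	CA(1)	1H	13C	0.109	3	-6.2	-6.4	-6.4	-4.0	-3.8	-1.3	-0.4	-6.0
15	HARe(2)	CA(2)	1H	13C	0.109	3	-11.0	-10.6	-11.0	-8.2	-8.3	-2.9	-0.6	-8.6
16	HARe(4)	CA(4)	1H	13C	0.109	3	-12.5	-12.5	-12.3	-9.1	-9.2	-3.1	-0.5	-9.1
17	HARe(6)	CA(6)	1H	13C	0.109	3	-8.6	-9.7	-9.6	-7.0	-6.9	-1.7	-0.4	-10.2
18	HARe(7)	CA(7)	1H	13C	0.109	3	-8.7	-8.5	-8.3	-4.4	-4.1	-1.3	-0.4	-7.3
19	HASi(1)	CA(1)	1H	13C	0.109	4	1.5	1.4	1.3	0.7	0.8	0.1	0.1	4.8
20	HASi(2)	CA(2)	1H	13C	0.109	4	6.9	7.1	7.0	6.5	6.0	0.9	0.3	5.2
21	HASi(5)	CA(5)	1H	13C	0.109	4	10.1	9.7	9.5	6.0	6.4	0.5	0.3	6.8
22	HASi(6)	CA(6)	1H	13C	0.109	4	7.1	6.1	6.1	3.8	3.4	0.7	0.1	5.8
23	HASi(7)	CA(7)	1H	13C	0.109	4	2.2	2.4	2.6	2.3	2.6	1.1	0.2	3.5
24	HARe(1)	HASi(1)	1H	1H	0.178	5	-1.5	-1.2	-1.1	0.1	0.3	-0.2	-0.1	0.9
25	HARe(2)	HASi(2)	1H	1H	0.178	5	1.1	0.6	0.6	0.3	0.1	-0.8	-0.1	1.3
26	HARe(3)	HASi(3)	1H	1H	0.178	5	-0.9	-1.4	-1.3	-2.0	-1.7	-0.6	0.1	-4.3
27	HARe(5)	HASi(5)	1H	1H	0.178	5	2.4	2.5	2.9	1.4	1.8	-0.6	0.1	1.2
28	HARe(6)	HASi(6)	1H	1H	0.178	5	-0.2	0.7	1.0	0.3	0.3	-0.2	-0.1	-2.5
29	HARe(7)	HASi(7)	1H	1H	0.178	5	-2.0	-2.1	-2.3	-0.9	-0.7	-0.3	-0.1	1.6
30	HG(1)	CG(1)	1H	13C	0.109	6	-1.2	-1.4	-1.0	-1.6	-1.4	-0.2	-0.0	3.6
31	HGRe(3)	CG(3)	1H	13C	0.109	6	-2.9	-3.3	-3.2	0.6	0.6	-0.3	-0.0	4.8
32	HGSi(3)	CG(3)	1H	13C	0.109	6	4.1	2.8	2.4	-5.3	-5.2	0.0	0.1	1.6
33	HGRe(3)	HGSi(3)	1H	1H	0.178	6	0.8	1.1	1.4	-3.0	-2.9	0.0	0.1	8.6
34	HD(3)	CD(3)	1H	13C	0.109	6	6.0	5.9	5.6	3.9	4.2	1.6	0.3	-5.3
35	HG(5)	CG(5)	1H	13C	0.109	6	-4.1	-4.2	-3.9	-2.2	-1.9	-0.9	-0.2	-11.4
36	HGRe(7)	CG(7)	1H	13C	0.109	6	-3.6	-4.0	-3.7	-1.7	-1.3	-0.3	-0.1	3.6
37	HGSi(7)	CG(7)	1H	13C	0.109	6	2.3	1.6	1.9	-1.0	-0.9	0.4	0.0	-7.4
38	HGRe(7)	HGSi(7)	1H	1H	0.178	6	-1.4	-1.1	-1.0	-1.8	-1.7	0.0	-0.0	0.4
39	HD(7)	CD(7)	1H	13C	0.109	6	6.0	5.8	5.7	2.7	2.8	1.1	0.3	2.3
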