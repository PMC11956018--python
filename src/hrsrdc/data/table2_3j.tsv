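id	dihedral	karplus_set	exp_ref45_hz	exp_ref24_hz	mdsol_hz	hrsr_hz	at0_hz	at0p1_hz	at1_hz	at10_hz	atremvac_hz
1	HB(1)-CB(1)-CA(1)-HASi(1)	HC_HC	2.8		2.6	2.7	2.6	2.7	3.3	3.9	5.2
2	HB(2)-CB(2)-CA(2)-HASi(2)	HC_HC	4.5	4.4	3.7	3.8	3.7	3.8	5.4	6.1	2.8
3	HB(3)-CB(3)-CA(3)-HASi(3)	HC_HC	4.5	4.2	3.9	4.0	3.9	4.0	3.9	4.4	3.7
4	HB(5)-CB(5)-CA(5)-HASi(5)	HC_HC	3.9	3.7	3.4	3.4	3.3	3.4	3.4	3.9	3.4
5	HB(6)-CB(6)-CA(6)-HASi(6)	HC_HC	3.8	4.1	3.3	3.2	3.3	3.1	5.4	6.7	2.5
6	HB(7)-CB(7)-CA(7)-HASi(7)	HC_HC	4.5		4.1	4.1	4.1	4.2	4.6	4.6	1.8
7	HB(1)-CB(1)-CG(1)-HG(1)	HC_HC	4.7	5.1	5.0	4.4	5.0	5.0	5.0	4.5	12.8
8	HB(5)-CB(5)-CG(5)-HG(5)	HC_HC	7.0	7.0	6.4	6.2	6.4	5.6	6.4	6.2	2.5
9	HN(2)-N(2)-CB(2)-HB(2)	HN_HC	9.2	9.1	9.2	9.2	9.2	9.2	8.8	8.5	8.3
10	HN(3)-N(3)-CB(3)-HB(3)	HN_HC	9.6	9.2	9.1	9.1	9.1	9.1	8.8	8.0	6.5
11	HN(4)-N(4)-CB(4)-HB(4)	HN_HC	9.3	9.0	9.3	9.3	9.3	9.3	8.8	8.5	7.0
12	HN(5)-N(5)-CB(5)-HB(5)	HN_HC	9.6	9.4	9.3	9.3	9.3	9.3	9.2	8.8	9.7
13	HN(6)-N(6)-CB(6)-HB(6)	HN_HC	8.7	8.6	9.2	9.2	9.2	9.2	8.5	8.0	9.7
14	HN(7)-N(7)-CB(7)-HB(7)	HN_HC	9.5	9.3	9.2	9.2	9.2	9.2	8.9	8.7	8.0
15	HB(1)-CB(1)-CA(1)-HARe(1)	HC_HC	11.5	11.7	11.9	11.8	11.9	11.8	10.7	10.2	12.3
16	HB(2)-CB(2)-CA(2)-HARe(2)	HC_HC	12.0	12.1	12.6	12.3	12.6	12.5	9.1	7.7	12.8
17	HB(3)-CB(3)-CA(3)-HARe(3)	HC_HC	12.3		12.5	12.6	12.5	12.6	10.8	9.5	12.9
18	HB(4)-CB(4)-CA(4)-HARe(4)	HC_HC	10.8	10.9	12.4	12.4	12.4	12.2	5.4	3.6	11.7
19	HB(5)-CB(5)-CA(5)-HARe(5)	HC_HC	12.3	12.2	12.5	12.6	12.5	12.5	11.6	10.7	12.9
20	HB(6)-CB(6)-CA(6)-HARe(6)	HC_HC	11.6	11.4	11.4	11.6	11.4	11.2	8.7	6.5	12.7
21	HB(7)-CB(7)-CA(7)-HARe(7)	HC_HC	10.0		9.4	9.6	9.4	9.4	9.8	9.7	11.6
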