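fragment	printed_mz	z	table	row	consistent
p[Ψ-CE]CCUC[I-CE]Gp	1202.137	2	psi	1	1
[Ψ-CE]UCCAUGp	1135.641	2	psi	3a	1
[Ψ-CE]CCCAU[m^1^G]Gp	1135.641	2	psi	3b	0
U[Ψ-CE]CCAUGp	1135.641	2	psi	4a	1
CU[Ψ-CE]CCGp	970.620	2	psi	4b	1
UCCCA[Ψ-CE][m^1^G]Gp	1315.179	2	psi	8	0
[Ψ-CE]CC[m^1^A]ACGp	1153.669	2	psi	11a	1
[m^2,2^G][Ψ-CE]CA[m^1^A]Gp	1035.163	2	psi	11b	1
AC[Ψ-CE]C[I-CE]Gp	1021.147	2	psi	12	1
UAUCA[Ψ-CE]AGp	1312.172	2	psi	25a	1
AA[Ψ-CE]UCCACGp	976.132	3	psi	25b	0
AAU[Ψ-CE]CCACGp	976.132	3	psi	26a	0
UAU[Ψ-CE]UCCGp	1288.660	2	psi	26b	1
ACA[Ψ-CE]CGp	994.141	2	psi	27a	1
C[m^2,2^G][Ψ-CE]CUGp	1004.640	2	psi	27b	1
ACAU[Ψ-CE]Gp	994.634	2	psi	28a	1
AUAC[Ψ-CE]CGp	1147.153	2	psi	28b	1
[Ψ-CE]ACCCUGp	1135.146	2	psi	29	1
[Ψ-CE][Cm]U[I-CE]CGp	990.129	2	psi	31a	0
[Ψ-CE]CU[cmnm^5^Um]AUGp	1186.615	2	psi	31b	0
[Ψ-CE]CUCAU[m^6^A]Gp	1307.175	2	psi	31c	1
C[Ψ-CE]U[ncm5U]Gp	847.104	2	psi	32	1
C[Cm][Ψ-CE]CCGp	977.138	2	psi	33a	1
AC[Ψ-CE]UUGp	983.120	2	psi	33b	1
[Ψ-CE]CA[m^5^C]Gp	836.623	2	psi	35a	1
[Ψ-CE]CAU[m^1^G]CGp	1001.646	2	psi	35b	0
[m^6^A]A[Ψ-CE]CUGp	1001.646	2	psi	39a	1
A[Ψ-CE]CCUUAGp	1300.669	2	psi	39b	0
[Ψ-CE]ACAU[m^7^G]Gp	1174.168	2	psi	40	1
U[Cm]U[I-CE]ACACAC[Ψ-CE]Gp	1312.181	2	psi	41	0
[m^7^G][Ψ-CE]CAUGp	1009.639	2	psi	47	1
AC[Ψ-CE][m^7^G]UGp	1009.632	2	psi	48a	1
AC[m^7^G]AU[Ψ-CE]Gp	1174.168	2	psi	48b	1
A[m^7^G]ACC[Ψ-CE]Gp	1174.168	2	psi	49	0
C[I-CE]UC[Ψ-CE]CGp	1162.152	2	psi	50	1
[m^5^U][Ψ-CE]CA[m^1^A]AUCUCGp	1189.163	3	psi	55	1
[m^1^A][Ψ-CE]ACCCCGp	1306.189	2	psi	59a	1
[m^1^A][Ψ-CE]CCCCUGp	1294.677	2	psi	59b	1
[m^1^A]C[Ψ-CE]CCCACUGp	1612.223	2	psi	60	0
[m^1^A]CCCCUACC[Ψ-CE]Gp	1176.164	2	psi	67a	0
[m^1^A]CCCUUACC[Ψ-CE]Gp	1176.164	2	psi	67b	0
UCACCU[Ψ-CE]Gp	1288.164	2	psi	71	1
CC[m^5^C][Ψ-CE]CCAOH	1081.677	2	psi	73	1
C[I-CE]ACU[m^1^G]p	1174.168	2	ino	5	0
CA[I-CE]CUGp	994.633	2	ino	6a	1
UCCC[I-CE]UGp	1135.641	2	ino	7	1
C[I-CE]CUUCAGp	1300.669	2	ino	24a	0
C[I-CE]CUC[Ψ-CE]Gp	1162.152	2	ino	24b	1
C[m^2,2^G]U[I-CE]Gp	864.120	2	ino	28a	1
C[m^2,2^G]C[I-CE]UGp	1016.643	2	ino	28b	1
[Ψ-CE][Cm]U[I-CE]CGp	1016.641	2	ino	34a	1
CU[I-CE]AUAACGp	1477.198	2	ino	34b	0
CU[cmnm^5^Um]UC[I-CE]CCCAGp	1205.823	2	ino	37	0
C[m^7^G][I-CE]UCCGp	1162.154	2	ino	46a	1
A[m^7^G][I-CE]CCCGp	1174.168	2	ino	46b	0
A[m^7^G]A[I-CE]CUGp	1186.166	2	ino	48	1
[m^1^A][I-CE]CCCCGp	1153.665	2	ino	59	1
[I-CE]CAAACGp	1170.640	2	ino	65	0
CU[I-CE]UCCGp	1135.639	2	ino	67	1
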