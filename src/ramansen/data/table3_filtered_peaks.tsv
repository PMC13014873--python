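wavenumber_cm1	catabolite	stage	refined_stage	bond_vibration	spatially_unique
881	Pheophorbide-a	early	early	w(CH) B-C, w(CH) A-B	0
1107	py-Pheophorbide-a	early	early	w(CH) D	0
1138	Pheophytin-a	early	early	w(CH) A-D, w(CH) D	0
1160	py-Pheophorbide-a	early	early	w(CH) A-D	0
1321	Pheophytin-a	early	early	rho(CH2) phytol	0
1346	Pheophytin-a	early	early	w(NH) A, w(CH) D	0
1366	Chlorophyllide-a	early	early	rho(CH2) (D)-CH2-CH2-COOH, w(CH) D	0
1369	Chlorophyll-a	early	early	rho(CH2) (D)-CH2-CH2-COOPhytol, w(CH) D	0
1374	Pheophorbide-a	early	early	rho(CH2) (B)-CH2-CH3, rho(CH3) B/C	0
1378	py-Pheophorbide-a	early	early	nu_s(CH3) (C)-CH3, w(NH) C, w(CH) D	0
1396	Chlorophyll-b	early	early	rho(CH2) (D)-chain, w(CH) D, rho(CH3) (A)-CH3	0
1406	Pheophorbide-a	early	early	rho(CH3) C/D, rho(CH2) (A)-CH=CH2	0
1430	Chlorophyll-b	early	early	nu(CH3) (A)-CH3	0
1435	Chlorophyllide-a	early	early	nu(CH3) (A)-CH3, nu(CH3) (D)-CH3	0
1445	ChlC-YTPP-1	late	late	rho(CH2) (D)-chain, nu(CH3) (D)-CH3, w(CH) A-D, w(NH) A	0
1460	NChlC	mid	mid	nu(CH3) (D)-CH3, nu_s(CH2) (D)-chain	0
1474	MV-MM	late	late	nu(CH3) ring-CH3, nu(NH) ring	0
1475	Pheophytin-a	early	early	nu(CH3) D/C, w(CH) B-C	0
1475	py-Pheophorbide-a	early	early	nu(CH3) A/C, nu_s(CH2) (D)-chain	0
1479	DNChlC	mid	mid	rho(CH2) A-D, nu(C-C) C-D, rho(CH2) (D)-chain	0
1489	Chlorophyll-b	early	early	nu(CH3) (A)-CH3	0
1490	DChlC-YTPP-1	late	late	nu(C=C) C-D, w(CH) ester chain, nu(CH3) -C=CH-COOCH3	1
1494	py-NChlC	mid	mid	nu(C-N-C) D, nu_s(CH2) (A)-CH2-(D), rho(CH2) (D)-chain	0
1495	C-E-RD	late	quasi-mid	nu(C=C) C, nu(CH3) (C)-CH3, w(NH) C, w(CH) (C)-CHO	1
1501	Chlorophyllide-a	early	early	nu(C=N) A, nu(CH3) (A)-CH3, nu(C-C) A, nu_s(CH2) A	0
1501	Chlorophyll-b	early	early	nu(C=N) A, nu(CH3) (D)-CH3, nu(C-C) A, nu_s(CH2) A	0
1510	bc-NChlC	late	late	rho(CH2) (B)-CH2-CH2-O-Glsy, rho(CH2) (D)-COO-CH2-Glsy	1
1510	DChlC-YTPP-2	late	late	nu(CH3) (D)-CH3, nu(C-C) D, rho(CH2) (D)-chain, nu(C=C) -C=CH-COOH	1
1531	pFChlC	mid	mid	nu(CH3) (C)-CH3, nu(C=C) C, nu(C-C) E	0
1535	C-E-RD	late	quasi-mid	nu(C-C) (C)-CHO, w(NH) C, nu(C=C) C, nu(CH3) (C)-CH3	1
1540	bc-FChlC	late	late	nu(CH3) (C)-CH3, nu(C=C) C, nu(C-N) C, nu(C-C) E	0
1541	Pheophorbide-a	early	early	nu(C=C) D-E, nu(C=N) C, nu(C-C) B	0
1566	Chlorophyllide-a	early	early	nu(C-C) A, nu(C-C) A-B	0
1567	Chlorophyll-a	early	early	nu(C-C) A, nu(C-C) A-B	0
1572	Chlorophyll-b	early	early	nu(C-C) A, gamma(C-C) B	0
1587	Pheophorbide-a	early	early	nu(C-N) C, w(NH) C, nu(C=C) B=C, nu(C=C) B, nu(C=N) B	0
1611	Pheophytin-a	early	early	nu(C-N) A, w(NH) A, nu(C-C) A	0
1616	DPiChlC	mid	mid	nu(C-N) D, nu(C=C) A-D	0
1619	bc-FChlC	late	late	nu(C-N) D, w(CH) A-D	0
1619	Chlorophyllide-a	early	early	nu(C=C) B, nu(C=C) B=C-C, nu(C=C) C	0
1619	PiChlC	mid	mid	nu(C-N) D, nu(C=C) A-D, nu(C-N) C	0
1623	Chlorophyll-a	early	early	nu(C=C) B-C, nu(C-N) B, nu(C=C) C	0
1629	Chlorophyll-b	early	early	nu(C-C) D-E, nu(C=C) C, nu(C=C) D	0
1631	py-Pheophorbide-a	early	early	nu(C=C) A-D, nu(C-C) C, nu(C=C) A-B	0
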