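wavenumber_cm1	bond_vibration	assignment
700	not identified	Chlorophyll-a
744	delta(N-C-C); gamma(C-OH) COOH	Chlorophyll-a; Pectins
854	C-O-C skeleton	Pectins (alpha-anomer)
898	H-C-C and H-CO bending; delta(C-C-H), delta(C-OH); delta(CH) aromatic	Cellulose (amorphous); Pectins (beta-anomer); Xylan
907	H-C-C and H-CO bending	Cellulose (crystalline)
917	not identified; nu(C-O-C) symm	Cellulose; Lignin
1003	rho(CH3) polyene; nu(C-C)	Carotenoids; Phenylalanine
1020	C-C-coupled rho(CH3) polyene	Carotenoids
1048	nu(C-O), nu(C-C), delta(C-OH); nu(CC)(CO)	Cellulose, Lignin; Pectins
1128	delta(C-O-C) + delta(C-C)	Xylan
1147	nu(CaN); nu(CaN) II, nu(CbCH3), delta(CaNCa) I	Pheophytin-a; Chlorophyll-a
1157	nu(C-C); nu(CaN); not identified	Carotenoids; Chlorophyll-a, Pheophytin-a; Lignin
1218	not identified	Lignin; Xylan
1226	delta(CmH)	Chlorophyll-a
1272	CH2-O-H related	alpha-D-glucose
1288	delta(CH2, CH3)	Aliphatics
1309	not identified	Carotenoids
1328	delta(CH3); nu(CaN)	Pectins; Chlorophyll-a
1343	delta(CH2, CH3); nu(CaN)	alpha-amyrin; Chlorophyll-a
1355	delta(CH2, CH3); nu(CaCb)	Aliphatics; Chlorophyll-a
1451	delta(CH2, CH3)	Aliphatics
1456	delta(CH2, CH3)	alpha-amyrin
1462	nu_s(CH2)	Cellulose (amorphous)
1481	nu_s(CH2)	Cellulose (crystalline)
1494	nu(CaCm)	Pheophytin-a
1525	nu(C=C)	Carotenoids
1606	nu(C-C) aromatic; nu(COO-) asymm	Lignin; Pectins
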