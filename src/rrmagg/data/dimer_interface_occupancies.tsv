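model	kind	res_a	atoms_a	atoms_b	res_b	occupancy
SaSb/D	hbond	Lys176	NZ-HZ*	OE1	Gln182	84.25
SaSb/D	hbond	Leu177	O	HD21-ND2	Asn179	67.49
SaSb/D	hbond	Asp174	OD2	HH*-NH*	Arg165	66.19
SaSb/D	hbond	Ser163	O	HE-NE	Arg165	61.19
SaSb/D	hbond	Asp174	OD1	HH*-NH*	Arg165	61.10
SaSb/D	hbond	Gln184	OE1	HH12-NH1	Arg227	59.77
SaSb/D	hbond	Asp185	OD1	HZ*-NZ	Lys145	55.37
SaSb/D	hbond	Asp174	OD1	HZ*-NZ	Lys176	39.71
SaSb/D	hbond	Gln182	OE1	H*-N*	Asn179	37.73
SaSb/D	hbond	Cys175	O	HZ*-NZ	Lys176	33.73
SaSb/D	hbond	Asp174	OD2	HZ*-NZ	Lys176	33.60
SaSb/D	hbond	Arg227	NH2-HH*	OE*	Glu261	28.51
SaSb/D	hydrophobic	Leu177	CD2	CD2	Phe147	88.36
SaSb/D	hydrophobic	Met162	CB	CD2	Leu109	84.51
SaSb/D	hydrophobic	Leu177	CD1	CD1	Phe147	73.50
SaSb/D	hydrophobic	Leu177	CD1	CD2	Phe147	68.80
SaSb/D	hydrophobic	Leu177	CD2	CZ	Phe149	56.31
SaSb/D	hydrophobic	Pro262	CD	CD	Pro225	54.98
SaSb/D	hydrophobic	Leu177	CD1	CZ	Phe147	42.82
SaSb/D	hydrophobic	Met162	CE	CD1	Leu109	33.71
SaSb/D	hydrophobic	Leu177	CD1	CD1	Leu109	30.98
SaSb/D	hydrophobic	Leu177	CD2	CD1	Phe147	20.75
SbSb/D	hbond	Asp185	N-H	O	Gly170	56.93
SbSb/D	hbond	Arg171	NH*-HH*	O	Ile257	39.28
SbSb/D	hbond	Glu186	OE*	H*-N*	Arg171	32.04
SbSb/D	hbond	Ser183	O	H-N	Trp172	30.28
SbSb/D	hbond	Ala228	N-H	O	Thr141	26.26
SbSb/D	hbond	Asn179	ND2-HD21	O	Trp172	25.77
SbSb/D	hbond	Arg171	NH1-HH1	O	Glu246	24.71
SbSb/D	hbond	Gln182	NE2-HE22	O	Trp172	23.45
SbSb/D	hbond	Asn259	O	HH*-NH*	Arg171	23.00
SbSb/D	hbond	Arg171	NH1-HH1	O	Pro178	20.57
SbSb/D	hydrophobic	Phe147	CD1	CZ	Phe147	94.88
SbSb/D	hydrophobic	Trp113	CD1	CZ	Phe194	90.63
SbSb/D	hydrophobic	Trp113	CD1	CD1	Phe194	71.93
SbSb/D	hydrophobic	Trp113	CD1	CD2	Phe194	70.50
SbSb/D	hydrophobic	Phe147	CD2	CZ	Phe147	64.14
SbSb/D	hydrophobic	Leu109	CD2	CZ	Phe147	49.35
SbSb/D	hydrophobic	Phe147	CZ	CZ	Phe147	46.07
SbSb/D	hydrophobic	Trp113	CE3	CZ	Phe229	45.86
SbSb/D	hydrophobic	Trp113	CZ2	CD1	Phe194	33.55
SbSb/D	hydrophobic	Trp113	CE3	CZ	Phe194	27.96
SbSb/D	hydrophobic	Leu109	CD2	CD1	Phe147	23.49
SbSb/D	hydrophobic	Leu109	CD1	CD2	Leu109	20.45
SbH1a1/D	hbond	Ser163	O	H*-N*	Arg197	73.84
SbH1a1/D	hbond	Ser125	O	H-N	Ser266	62.39
SbH1a1/D	hbond	Asp185	OD1	H*-N*	Arg165	55.27
SbH1a1/D	hbond	Asp174	OD2	HZ*-NZ	Lys136	51.10
SbH1a1/D	hbond	Asn267	O	HH*-NH*	Arg171	46.94
SbH1a1/D	hbond	Gln182	O	HH*-NH2	Arg171	46.52
SbH1a1/D	hbond	Asp185	OD2	H*-N*	Arg165	43.98
SbH1a1/D	hbond	Gln164	NE2-HE21	O	Ala228	42.95
SbH1a1/D	hbond	Met162	O	HZ*-NZ	Lys136	34.79
SbH1a1/D	hbond	Ser266	O	HH*-NH1	Arg171	32.29
SbH1a1/D	hbond	Gln164	OE1	HE2-NE2	His256	30.74
SbH1a1/D	hydrophobic	Phe127	CZ	CD2	Phe229	92.20
SbH1a1/D	hydrophobic	Trp172	CZ3	CB	Ala228	90.93
SbH1a1/D	hydrophobic	Leu177	CD1	CD2	Phe147	77.41
SbH1a1/D	hydrophobic	Leu177	CD1	CD2	Leu109	55.16
SbH1a1/D	hydrophobic	Leu177	CD1	CD1	Phe147	38.18
SbH1a1/D	hydrophobic	Val159	CG1	CE1	Phe149	27.95
SbH1a1/D	hydrophobic	Leu177	CD1	CD1	Leu109	25.86
SbH1a1/D	hydrophobic	Val159	CG1	CE1	Phe149	23.79
SbH1a2/D	hbond	Arg165	NH2-HH22	O	Asn259	62.26
SbH1a2/D	hbond	Trp172	NE1-HE1	O	Glu261	52.92
SbH1a2/D	hbond	Arg165	NH2-HH21	OG	Ser258	51.93
SbH1a2/D	hbond	Tyr155	OH-HH	O	Lys145	23.63
SbH1a2/D	hydrophobic	Val159	CG1	CD2	Phe147	79.74
SbH1a2/D	hydrophobic	Val159	CG1	CD1	Phe147	73.65
SbH1a2/D	hydrophobic	Val159	CG1	CD2	Leu109	71.89
SbH1a2/D	hydrophobic	Val159	CG2	CD1	Phe147	61.31
SbH1a2/D	hydrophobic	Met167	CE	CD1	Leu188	50.17
SbH1a2/D	hydrophobic	Met167	CE	CD2	Leu188	47.86
SbH1a2/D	hydrophobic	Trp172	CD1	CB	Pro262	48.54
SbH1a2/D	hydrophobic	Trp172	CD1	CD	Pro262	36.94
SbH1a2/D	hydrophobic	Val159	CG1	CZ	Phe147	36.02
SbH1a2/D	hydrophobic	Val159	CG2	CD2	Phe147	34.38
SbH1a2/D	hydrophobic	Val159	CG1	CD2	Leu109	26.98
SbH1a2/D	hydrophobic	Val159	CG2	CZ	Phe147	25.94
H1H1/D	hbond	Met167	O	HE21-NE2	Gln164	70.14
H1H1/D	hbond	Ile168	O	H-N	Met167	65.99
H1H1/D	hbond	Lys114	NZ-HZ*	O	Met167	59.12
H1H1/D	hbond	Glu122	OE*	HH22-NH2	Arg165	20.71
H1H1/D	hydrophobic	Ile168	CG2	CH2	Trp172	80.31
H1H1/D	hydrophobic	Tyr123	CD2	CH2	Trp172	32.52
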