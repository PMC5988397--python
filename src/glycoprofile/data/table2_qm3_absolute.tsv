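label	step	model	functional	basis	solvent	energy_au	charge
ES	fructosylation	QM3	B3LYP	6-31+G(d)	CPCM(eps=80)	-6018.936815	-2
TS1	fructosylation	QM3	B3LYP	6-31+G(d)	CPCM(eps=80)	-6018.907247	-2
IM1	fructosylation	QM3	B3LYP	6-31+G(d)	CPCM(eps=80)	-6018.921811	-2
IM2	hydrolysis	QM3	B3LYP	6-31+G(d)	CPCM(eps=80)	-5943.226656	-2
TS2	hydrolysis	QM3	B3LYP	6-31+G(d)	CPCM(eps=80)	-5943.201925	-2
PC2	hydrolysis	QM3	B3LYP	6-31+G(d)	CPCM(eps=80)	-5943.250060	-2
IM3	transfructosylation	QM3	B3LYP	6-31+G(d)	CPCM(eps=80)	-6094.608459	-2
TS3	transfructosylation	QM3	B3LYP	6-31+G(d)	CPCM(eps=80)	-6094.571815	-2
PC3	transfructosylation	QM3	B3LYP	6-31+G(d)	CPCM(eps=80)	-6094.594087	-2
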