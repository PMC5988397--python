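label	step	model	dE_cpcm	dE_gas
RC	fructosylation	QM1	0.0	0.0
TS1	fructosylation	QM1	18.2	12.1
IM1	fructosylation	QM1	0.6	-0.8
IM2	hydrolysis	QM1	0.0	0.0
TS2	hydrolysis	QM1	19.4	13.0
PC2	hydrolysis	QM1	-12.3	-19.6
IM3	transfructosylation	QM1	0.0	0.0
TS3	transfructosylation	QM1	24.9	18.0
PC3	transfructosylation	QM1	1.1	-6.9
RC	fructosylation	QM2	0.0	0.0
TS1	fructosylation	QM2	19.0	4.2
IM1	fructosylation	QM2	7.8	-5.0
IM2	hydrolysis	QM2	0.0	0.0
TS2	hydrolysis	QM2	17.5	17.0
PC2	hydrolysis	QM2	-14.5	-5.3
IM3	transfructosylation	QM2	0.0	0.0
TS3	transfructosylation	QM2	22.6	17.9
PC3	transfructosylation	QM2	7.4	8.2
RC	fructosylation	QM3	0.0	0.0
TS1	fructosylation	QM3	18.6	7.4
IM1	fructosylation	QM3	9.4	0.7
IM2	hydrolysis	QM3	0.0	0.0
TS2	hydrolysis	QM3	15.5	15.1
PC2	hydrolysis	QM3	-14.7	-7.5
IM3	transfructosylation	QM3	0.0	0.0
TS3	transfructosylation	QM3	23.0	19.1
PC3	transfructosylation	QM3	9.0	11.2
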