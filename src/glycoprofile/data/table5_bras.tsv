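functional	dG_diss	act_hydrolysis	rxn_hydrolysis	act_transfructosylation	rxn_transfructosylation
B3LYP	3.1	20.8	-9.8	26.2	11.5
M06-2X	3.3	24.9	-7.7	29.8	10.6
B97D	3.1	20.8	-6.5	23.6	12.0
wB97XD	3.1	24.9	-7.4	27.6	10.9
MPWB1K	3.3	22.5	-8.8	29.4	12.8
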