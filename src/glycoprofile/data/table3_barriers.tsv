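functional	dE1	dE2	dE3	ddE
B3LYP	17.5	17.6	23.0	5.4
M06-2X	21.1	22.6	27.5	4.9
B97D	16.7	14.8	17.7	2.9
wB97XD	19.5	20.1	22.7	2.6
MPWB1K	19.2	20.0	27.0	7.0
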