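study	n_subjects	n_female	n_cases	n_asthma	n_european_american	n_latino	n_african_american
CHS	2881	1344	1096	1206	1552	1329	0
CAMP	384	142	199	384	384	0	0
CAG/CSGA/SARP	283	150	245	283	98	0	185
GALA1	521	230	434	521	0	521	0
MCCAS	476	198	250	476	0	476	0
GRAAD	809	474	377	228	0	0	809
SAPPHIRE	279	219	111	148	0	0	279
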