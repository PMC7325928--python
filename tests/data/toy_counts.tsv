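otu_id	N1	N2	F1	HC1	EC1	AC1
OTU01	64716	25000	250	3	2	0
OTU02	2000	1500	40	0	0	0
OTU03	2	1	1	0	0	0
OTU04	600	700	1500	450	380	5
OTU05	40	60	100	30	25	0
OTU06	100	120	400	60	50	300
OTU07	500	400	80	0	0	0
OTU08	200	150	30	0	0	0
OTU09	100	80	20	0	0	0
OTU10	2	1	2	0	0	0
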