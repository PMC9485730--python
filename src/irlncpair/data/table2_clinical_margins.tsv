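item	level	count	percent
Gender	Female	33	18.44
Gender	Male	146	81.56
Tobacco	Yes	114	63.69
Alcohol	Yes	106	59.22
T stage	T1	12	6.7
T stage	T2	27	15.08
T stage	T3	110	61.45
T stage	T4	30	16.76
N stage	N0	83	46.37
N stage	N1	62	34.64
N stage	N2	22	12.29
N stage	N3	12	6.7
TNM stage	Stage I	10	5.59
TNM stage	Stage II	77	43.02
TNM stage	Stage III	92	51.4
Tumor grade	Poorly	49	27.37
Tumor grade	Moderately	98	54.75
Tumor grade	Well	32	17.88
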