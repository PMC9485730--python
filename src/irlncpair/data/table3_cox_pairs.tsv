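pair	model	beta	se	hr	hr_lo	hr_hi	p
LINC01121|FAM167A-AS1	Univariate	0.789	0.237	2.201	1.385	3.5	0.001
ADAMTS9-AS2|MGC12916	Univariate	0.664	0.288	1.943	1.105	3.418	0.021
MIR124-2HG|FAM167A-AS1	Univariate	0.567	0.196	1.764	1.202	2.588	0.004
LINC00942|ADAMTS9-AS2	Univariate	-0.84	0.424	0.432	0.188	0.991	0.048
PURPL|FAM167A-AS1	Univariate	0.598	0.249	1.819	1.117	2.961	0.016
ZNF503-AS1|H19	Univariate	2.662	1.041	14.327	1.863	110.187	0.011
LINC01121|FAM167A-AS1	Multivariate	0.687	0.252	1.989	1.213	3.259	0.006
ADAMTS9-AS2|MGC12916	Multivariate	0.863	0.293	2.371	1.335	4.211	0.003
MIR124-2HG|FAM167A-AS1	Multivariate	0.419	0.209	1.52	1.009	2.291	0.045
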