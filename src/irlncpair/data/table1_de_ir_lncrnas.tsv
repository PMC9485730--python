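gene	logFC	AveExpr	t	p	adj_p	change
LINC01121	-1.196	3.898	-3.679	0.001	0.318	Down
LINC00592	-1.306	7.669	-2.93	0.006	0.589	Down
CTD-3080P12.3	-1.076	3.852	-2.595	0.015	0.589	Down
WAKMAR2	-1.041	7.665	-2.569	0.016	0.589	Down
H19	-1.902	8.538	-2.536	0.017	0.589	Down
DLGAP4-AS1	-0.982	5.319	-2.497	0.018	0.589	Down
SCAT1	-1.459	5.612	-2.487	0.019	0.589	Down
LOC101928557	-1.139	4.483	-2.417	0.022	0.589	Down
PURPL	-1.619	3.829	-2.403	0.023	0.589	Down
IQCF5-AS1	-1.061	3.662	-2.302	0.029	0.641	Down
ELFN2	-1.126	6.26	-2.291	0.029	0.641	Down
MIR124-2HG	-0.991	4.119	-2.217	0.034	0.69	Down
LINC01102	-1.018	2.774	-2.088	0.046	0.825	Down
LOC101928389	-1.09	3.768	-2.048	0.05	0.825	Down
ADAMTS9-AS2	1.714	5.225	4.129	0	0.187	Up
SOX2-OT	1.731	5.417	2.935	0.006	0.589	Up
GRK3-AS1	1.601	3.371	2.864	0.008	0.589	Up
DELEC1	1.11	3.089	2.691	0.012	0.589	Up
FAM167A-AS1	1.391	3.184	2.536	0.017	0.589	Up
ZNF503-AS1	1.112	7.336	2.532	0.017	0.589	Up
RNF217-AS1	0.984	5.366	2.486	0.019	0.589	Up
MGC12916	1.079	4.97	2.446	0.021	0.589	Up
LOC101927798	1.036	5.289	2.409	0.022	0.589	Up
LINC00551	1.432	6.052	2.391	0.023	0.589	Up
LINC00942	1.545	6.705	2.109	0.044	0.824	Up
FSIP2-AS2	1.335	5.226	2.081	0.046	0.825	Up
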