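name	sequence	kd_nM	kd_err_nM	dg_kcal	dg_err_kcal
p53-WT	QETFSDLWKLLP	1543.2	90	-7.79	0.03
p53-P27S	QETFSDLWKLLS	75.76	10.45	-9.54	0.08
p53-P27N	QETFSDLWKLLN	168	9.24	-9.076	0.27
12/1	MPRFMDYWEGLN	239.8	53.7	-8.87	0.12
12/1-N12S	MPRFMDYWEGLS	18.83	5.03	-10.35	0.14
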