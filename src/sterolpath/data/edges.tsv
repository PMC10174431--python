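substrate	product	symbol
acetyl-CoA	acetoacetyl-CoA	ACAT
acetoacetyl-CoA	HMG-CoA	HMGS
HMG-CoA	mevalonate	HMGR
mevalonate	mevalonate-5-P	MK
mevalonate-5-P	mevalonate-5-PP	PMK
mevalonate-5-PP	IPP	MPDC
IPP	DMAPP	IPI
DMAPP	GPP	GPS
GPP	FPP	FPS
FPP	squalene	SQS
squalene	2,3-epoxysqualene	SQE
squalene	2,3-epoxysqualene	AltSQE
2,3-epoxysqualene	lanosterol	LAS
2,3-epoxysqualene	cycloartenol	CAS
lanosterol	4,4-dimethylcholesta-8,14,24-trienol	CYP51G1
4,4-dimethylcholesta-8,14,24-trienol	14-demethyllanosterol	FK
14-demethyllanosterol	4alpha-carboxy-4-methylzymosterol	SMO
4alpha-carboxy-4-methylzymosterol	3-keto-4-methylzymosterol	NSDHL
3-keto-4-methylzymosterol	4alpha-methylzymosterol	HSD17B7
4alpha-methylzymosterol	4alpha-carboxyzymosterol	SMO
4alpha-carboxyzymosterol	3-ketozymosterol	NSDHL
3-ketozymosterol	zymosterol	HSD17B7
zymosterol	cholesta-7,24-dienol	HYD1
cholesta-7,24-dienol	7-dehydrodesmosterol	STE1
7-dehydrodesmosterol	desmosterol	DWF5
desmosterol	cholesterol	DWF1
zymosterol	zymostenol	DWF1
zymostenol	lathosterol	HYD1
lathosterol	7-dehydrocholesterol	STE1
7-dehydrocholesterol	cholesterol	DWF5
cycloartenol	24-methylenecycloartanol	SMT
24-methylenecycloartanol	4alpha-carboxy-24-methylenecycloartanol	SMO
4alpha-carboxy-24-methylenecycloartanol	3-keto-24-methylenecycloartanol	NSDHL
3-keto-24-methylenecycloartanol	cycloeucalenol	HSD17B7
cycloeucalenol	obtusifoliol	CPI1
obtusifoliol	4alpha-methyl-ergosta-8,14,24(28)-trienol	CYP51G1
4alpha-methyl-ergosta-8,14,24(28)-trienol	4alpha-methylfecosterol	FK
4alpha-methylfecosterol	24-methylenelophenol	HYD1
24-methylenelophenol	24-ethylidenelophenol	SMT
24-ethylidenelophenol	4alpha-carboxy-24-ethylidenelophenol	SMO
4alpha-carboxy-24-ethylidenelophenol	3-keto-24-ethylidenelophenol	NSDHL
3-keto-24-ethylidenelophenol	delta-7-avenasterol	HSD17B7
delta-7-avenasterol	5-dehydroavenasterol	STE1
5-dehydroavenasterol	isofucosterol	DWF5
isofucosterol	sitosterol	DWF1
sitosterol	stigmasterol	CYP710A
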