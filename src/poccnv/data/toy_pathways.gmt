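SET_HEME	synthetic hemoglobin-assembly-like set	GENE004	GENE005	GENE007	GENE010	GENE024	GENE026	GENE035	GENE038	GENE042	GENE053
SET_REDOX	synthetic oxygen-transport-redox-like set	GENE003	GENE005	GENE006	GENE014	GENE027	GENE028	GENE033	GENE059
SET_MEIOSIS	synthetic meiosis-like set	GENE004	GENE006	GENE008	GENE015	GENE028	GENE036	GENE037	GENE041	GENE053
SET_MTOR	synthetic mTOR-signalling-like set	GENE003	GENE004	GENE009	GENE010	GENE015	GENE019	GENE026	GENE027	GENE036	GENE037	GENE038	GENE059	GENE060
SET_INFLAM	synthetic inflammasome-like set	GENE007	GENE008	GENE012	GENE013	GENE020	GENE036	GENE037	GENE038	GENE041	GENE044	GENE053	GENE059
SET_TGFB	synthetic TGF-beta-like set	GENE004	GENE005	GENE007	GENE014	GENE032	GENE036	GENE037	GENE040	GENE044	GENE046
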