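degron_class	name	sequence
D_ext	dref1	RAALSDIGN
D_ext	dref2	RTVLEDLSN
D_ext	dref3	RQALGSVTN
D_ext	dref4	RSPLKAIEN
D_ext	dref5	RNELSGVDN
D_min	dref1	RAAL
D_min	dref2	RTVL
D_min	dref3	RQAL
D_min	dref4	RSPL
D_min	dref5	RNEL
KEN	kref1	KEN
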