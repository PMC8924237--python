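rsid	risk_allele	proxy_rsid	proxy_r2	proxy_risk_allele
rs10744861	A	rs1816225	0.86	A
rs3118053	A
rsFILLME03	A
rsFILLME04	A
rsFILLME05	A
rsFILLME06	A
rsFILLME07	A
rsFILLME08	A
rsFILLME09	A
rsFILLME10	A
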