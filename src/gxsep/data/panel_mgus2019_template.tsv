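rsid	risk_allele	proxy_rsid	proxy_r2	proxy_risk_allele
rsFILLME01	A	rs74998556	0.73	A
rsFILLME02	A
rsFILLME03	A
rsFILLME04	A
rsFILLME05	A
rsFILLME06	A
rsFILLME07	A
rsFILLME08	A
rsFILLME09	A
rsFILLME10	A
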