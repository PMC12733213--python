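country,lambda,source,gdp_multiple
Singapore,50000,explicit,
USA,150000,explicit,
China,30000,explicit,
UK,30000,explicit,
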