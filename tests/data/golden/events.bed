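g000_cL	94	212	g000.iso00.r00	exclusion	2
g000_cL	212	555	g000.iso00.r00	exclusion	1
g003_cL	446	819	g003.iso00.r00	exclusion	4
g005_cL	135	461	g005.iso00.r01	exclusion	4
g007_cL	420	616	g007.iso00.r00	exclusion	2
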