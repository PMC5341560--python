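gene_id	class	n_events	events	support	reads
g000.iso00.r00	0	0	.	2	g000.iso00.r00,g000.iso00.r03
g000.iso00.r00	1	1	exclusion:94-212	2	g000.iso01.r00,g000.iso01.r03
g000.iso00.r00	2	1	exclusion:212-555	1	g000.iso02.r00
g001.iso00.r03	0	0	.	1	g001.iso00.r03
g002.iso00.r00	0	0	.	1	g002.iso00.r00
g003.iso00.r00	0	1	exclusion:446-819	4	g003.iso01.r00,g003.iso01.r01,g003.iso01.r02,g003.iso01.r03
g003.iso00.r00	1	0	.	2	g003.iso00.r00,g003.iso00.r03
g004.iso00.r00	0	0	.	4	g004.iso00.r00,g004.iso00.r01,g004.iso00.r02,g004.iso00.r03
g005.iso00.r01	0	1	exclusion:135-461	4	g005.iso01.r00,g005.iso01.r01,g005.iso01.r02,g005.iso01.r03
g005.iso00.r01	1	0	.	2	g005.iso00.r01,g005.iso00.r02
g006.iso00.r02	0	0	.	2	g006.iso00.r02,g006.iso00.r03
g007.iso00.r00	0	1	exclusion:420-616	2	g007.iso01.r00,g007.iso01.r01
g007.iso00.r00	1	0	.	1	g007.iso00.r00
g008.iso00.r00	0	0	.	1	g008.iso00.r00
g009.iso00.r03	0	0	.	1	g009.iso00.r03
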