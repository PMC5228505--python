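strain	raw_pairs	clean_pairs
199hm	13899445	12843053
A-R4-D6	14575684	13452316
JBAF33	15061239	13296427
JBCS23	14432210	13216644
JBL14	15494585	14447147
JBM08	15431398	11578366
JBM10	19351386	17745650
JBMS11	14150502	13156769
JBNZ39	16079979	14219198
LO244K-D	18662530	8414623
FU22KAK	17828441	8627549
JBC07	13841037	12796750
JBNZ41	18752714	17332930
LO226KS	19572799	17917338
LO234KE	13310559	11256835
DS	15822091	14917952
PR26KG	17915043	17284316
WA34KE	22107199	18106322
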