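fragment	name	sequence
vector	E31_Fw	ctagtgcttcagCGTAAGGGGCAAG
vector	E31_Rv	gataaccactcgMNNCAAAGTGTAACCCGTC
B	T77_Fw	cgagtggttatcTTGAGCCGCCATG
B	T77_Rv	catagaagccgccCATCAGMNNCACTAATTGCGC
C	K139_Fw	ggcggcttctatgGTGATTATTTCCG
C	K139_Rv	gaaacagtggatcAACCTTMNNCAAATCAGCCTG
D	G187_Fw	gatccactgtttcACCCCGTCGAAG
D	G187_Rv	cagtgaaattgagAATCTCMNNCATCTGGGCAAATG
E	V298_Fw	ctcaatttcactgCTTCCCCCTATTGC
E	V298_Rv	ctgaagcactagCGCCGTMNNAATCTGTTGCAAC
sublibrary	D52_Rv	ccacttatccggTGTGACMNNATTCATTAACTCTG
sublibrary	T77_Fw'	ccggataagtggCCTCAATGGCCGGTAC
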