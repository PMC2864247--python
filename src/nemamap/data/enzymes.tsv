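# Default restriction-enzyme panel: 30 reliable, inexpensive single-cut enzymes
# name	site	cut_offset
DraI	TTTAAA	3
HindIII	AAGCTT	1
SalI	GTCGAC	1
SacI	GAGCTC	5
EcoRI	GAATTC	1
EcoRV	GATATC	3
BamHI	GGATCC	1
XbaI	TCTAGA	1
PstI	CTGCAG	5
KpnI	GGTACC	5
SmaI	CCCGGG	3
XhoI	CTCGAG	1
NcoI	CCATGG	1
NdeI	CATATG	2
SpeI	ACTAGT	1
SphI	GCATGC	5
ApaI	GGGCCC	5
NheI	GCTAGC	1
BglII	AGATCT	1
ScaI	AGTACT	3
StuI	AGGCCT	3
NsiI	ATGCAT	5
MfeI	CAATTG	1
HpaI	GTTAAC	3
SspI	AATATT	3
ClaI	ATCGAT	2
AflII	CTTAAG	1
AseI	ATTAAT	2
AvrII	CCTAGG	1
BclI	TGATCA	1
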