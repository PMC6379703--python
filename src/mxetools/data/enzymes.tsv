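name	recognition	cut_top	cut_bottom
MboI	GATC	0	4
AluI	AGCT	2	2
HinP1I	GCGC	1	3
HhaI	GCGC	3	1
TaqI	TCGA	1	3
HaeIII	GGCC	2	2
RsaI	GTAC	2	2
MseI	TTAA	1	3
EcoRI	GAATTC	1	5
HindIII	AAGCTT	1	5
BamHI	GGATCC	1	5
EcoRV	GATATC	3	3
SmaI	CCCGGG	3	3
SfoI	GGCGCC	3	3
PshAI	GACNNNNGTC	5	5
NheI	GCTAGC	1	5
NotI	GCGGCCGC	2	6
XhoI	CTCGAG	1	5
PstI	CTGCAG	5	1
KpnI	GGTACC	5	1
SpeI	ACTAGT	1	5
SacI	GAGCTC	5	1
XbaI	TCTAGA	1	5
SalI	GTCGAC	1	5
NcoI	CCATGG	1	5
ScaI	AGTACT	3	3
DraI	TTTAAA	3	3
SspI	AATATT	3	3
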