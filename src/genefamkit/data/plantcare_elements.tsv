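name	consensus	category
as-1	TGACG	stress
DRE	RCCGAC	stress
MYC	CATTTG	stress
MYB	CAACAG	stress
MBS	CAACTG	stress
ARE	AAACCA	stress
LTR	CCGAAA	stress
TCA	CCATCTTTTT	hormone
TGA-element	AACGAC	hormone
AuxRR-core	GGTCCAT	hormone
GARE-motif	TCTGTTG	hormone
P-box	CCTTTTG	hormone
TATC-box	TATCCCA	hormone
CGTCA-motif	CGTCA	hormone
TGACG-motif	TGACG	hormone
ERE	ATTTCAAA	hormone
ABRE	ACGTG	hormone
G-box	CACGTG	light
Box-4	ATTAAT	light
W-box	TTGACC	stress
WUN-motif	AAATTTCCT	stress
WRE3	CCACCT	stress
TCT-motif	TCTTAC	light
Box S	AGCCACC	stress
circadian	CAANNNNATC	other
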