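element_name	iupac_pattern	category
ARE	AAACCA	stress
MBS	CAACTG	stress
LTR	CCGAAA	stress
TC-rich_repeats	ATTCTCTAAC	stress
W-box	TTGACC	stress
WRE3	CCACCT	stress
STRE	AGGGG	stress
DRE-core	GCCGAC	stress
MYC	CATGTG	stress
GC-motif	CCCCCG	stress
ABRE	ACGTG	hormone
CGTCA-motif	CGTCA	hormone
TGACG-motif	TGACG	hormone
TCA-element	CCATCTTTTT	hormone
GARE-motif	TCTGTTG	hormone
P-box	CCTTTTG	hormone
TATC-box	TATCCCA	hormone
AuxRR-core	GGTCCAT	hormone
TGA-element	AACGAC	hormone
ERE	ATTTCAAA	hormone
ABRE3a	TACGTG	hormone
CAT-box	GCCACT	growth
O2-site	GATGACATGG	growth
GCN4-motif	TGAGTCA	growth
circadian	CAANNNNATC	growth
RY-element	CATGCATG	growth
MSA-like	TCCAACGG	growth
HD-Zip-1	CAATWATTG	growth
AAGAA-motif	GAAAGAA	growth
CCGTCC-box	CCGTCC	growth
E2Fb	GCGGGAAA	growth
Box-4	ATTAAT	growth
G-box	CACGTY	growth
GT1-motif	GGTTAA	growth
I-box	GATAAGG	growth
TCT-motif	TCTTAC	growth
Sp1	GGGCGG	growth
AE-box	AGAAACAA	growth
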