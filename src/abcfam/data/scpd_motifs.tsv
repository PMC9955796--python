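# Editable default motif dictionary: name	IUPAC consensus	stress flag (1 = stress-response regulator)
# Yeast-style cis-element consensi shipped as external defaults; replace freely.
GCN4	TGACTC	1
GCR1	CTTCCT	1
ADR1	TTGGRG	1
STRE	AGGGG	1
HSTF	TTCTAGAA	1
PHO4	CACGTG	1
GC/FAR	GGGGCGGG	1
ABF1	RTCAYAACG	1
TATA	TATAAA	0
CAAT	CCAATC	0
MCB	ACGCGT	0
SCB	CACGAAA	0
RAP1	RMACCCA	0
MCM1	TTTCCTAA	0
GAL4	CGGAGGAC	0
MIG1	ATSYGGGG	0
REB1	TTACCCGG	0
PDR1	TCCGCGGA	0
PDR3	TCCGTGGA	0
YAP1	TTACTAA	0
HAP2	TGATTGGT	0
INO2	CATGTGAA	0
INO4	CATTTGAC	0
ROX1	CCATTGTT	0
MSN4	CCCCTTA	0
LEU3	GCCGGTAC	0
CBF1	GTCACATG	0
STE12	TGAAACA	0
RLM1	CTAAATAG	0
SWI5	TGCTGA	0
ACE2	GCTGGT	0
XBP1	CTTCGAG	0
CRZ1	GAGGCTCA	0
ARO80	TGCGGGAT	0
GLN3	GATAAG	0
DAL80	TTGATAAT	0
UME6	AGCCGCCG	0
HAP1	CCGATAGA	0
SKN7	GGCCGGCC	0
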