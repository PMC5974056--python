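gene_symbol	occ_direction	prog_direction
HLA-DRB5	hyper	hypo
HLA-DQB1	hyper	hypo
TAPT1	hyper	hypo
TNNI3	hyper	hypo
ZCCHC12	hyper	hypo
TNNT1	hyper	hypo
CDYL	hypo	hyper
CYP1A1	hypo	hyper
KCNQ1	hypo	hyper
TUBGCP6	hypo	hyper
CSTA	hypo	hyper
P2RX5	hypo	hyper
CACNA2D4	hypo	hyper
TAF4	hypo	hyper
MYOZ3	hypo	hyper
FMOD	hypo	hyper
CYHR1	hypo	hyper
KIFC2	hypo	hyper
PSTPIP2	hypo	hyper
OTUD6B	hypo	hyper
TRANK1	hypo	hyper
WDR41	hypo	hyper
GPC5	hypo	hyper
VCX	hypo	hyper
RAB11B	hypo	hyper
HCN2	hypo	hyper
LHX3	hypo	hyper
THADA	hypo	hyper
DDR1	hyper	hyper
HLA-DQA1	hypo	hypo
LOC255167	hyper	hyper
RAD51L1	hyper	hyper
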