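gene_symbol	stage
BGN	occurrence
CD80	occurrence
IGSF21	occurrence
KIF1B	occurrence
LOX	occurrence
RBM47	occurrence
RESP18	occurrence
SAMD9	occurrence
SMTNL2	occurrence
SNED1	occurrence
ZC3H12D	occurrence
ATP8A2	progression
BRUNOL4	progression
C1orf127	progression
CES1	progression
GIPC2	progression
HECW2	progression
HLA-DRB1	progression
IGLON5	progression
IQSEC3	progression
LOC222699	progression
LOC284379	progression
MAD1L1	progression
OR5A1	progression
RALYL	progression
RFPL2	progression
SLC12A7	progression
TAGLN3	progression
TANC1	progression
TGFB3	progression
ZNF92	progression
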