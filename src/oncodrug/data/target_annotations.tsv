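gene_symbol	location	family	subfamily
MS4A1	plasma membrane	Antigen	Antigen
CD33	plasma membrane	Antigen	Antigen
CD52	plasma membrane	Antigen	Antigen
CD19	plasma membrane	Antigen	Antigen
CD3D	plasma membrane	Antigen	Antigen
EGFR	plasma membrane	Enzyme	Tyrosine kinase
ERBB2	plasma membrane	Enzyme	Tyrosine kinase
ERBB4	plasma membrane	Enzyme	Tyrosine kinase
KDR	plasma membrane	Enzyme	Tyrosine kinase
FLT1	plasma membrane	Enzyme	Tyrosine kinase
FLT3	plasma membrane	Enzyme	Tyrosine kinase
FLT4	plasma membrane	Enzyme	Tyrosine kinase
KIT	plasma membrane	Enzyme	Tyrosine kinase
PDGFRA	plasma membrane	Enzyme	Tyrosine kinase
PDGFRB	plasma membrane	Enzyme	Tyrosine kinase
CSF1R	plasma membrane	Enzyme	Tyrosine kinase
FGFR1	plasma membrane	Enzyme	Tyrosine kinase
FGFR2	plasma membrane	Enzyme	Tyrosine kinase
FGFR3	plasma membrane	Enzyme	Tyrosine kinase
RET	plasma membrane	Enzyme	Tyrosine kinase
MET	plasma membrane	Enzyme	Tyrosine kinase
ALK	plasma membrane	Enzyme	Tyrosine kinase
TEK	plasma membrane	Enzyme	Tyrosine kinase
DDR2	plasma membrane	Enzyme	Tyrosine kinase
NTRK1	plasma membrane	Enzyme	Tyrosine kinase
EPHA2	plasma membrane	Enzyme	Tyrosine kinase
IFNAR1	plasma membrane	Receptor	Transmembrane receptor
IFNAR2	plasma membrane	Receptor	Transmembrane receptor
IL2RA	plasma membrane	Receptor	Transmembrane receptor
IL2RB	plasma membrane	Receptor	Transmembrane receptor
IL2RG	plasma membrane	Receptor	Transmembrane receptor
TLR7	plasma membrane	Receptor	Transmembrane receptor
TLR8	plasma membrane	Receptor	Transmembrane receptor
TNFRSF8	plasma membrane	Receptor	Transmembrane receptor
CTLA4	plasma membrane	Receptor	Transmembrane receptor
PDCD1	plasma membrane	Receptor	Transmembrane receptor
FCGR1A	plasma membrane	Receptor	Transmembrane receptor
PRLR	plasma membrane	Receptor	Transmembrane receptor
GNRHR	plasma membrane	Receptor	G-protein coupled receptor
LHCGR	plasma membrane	Receptor	G-protein coupled receptor
SMO	plasma membrane	Receptor	G-protein coupled receptor
SSTR2	plasma membrane	Receptor	G-protein coupled receptor
SSTR5	plasma membrane	Receptor	G-protein coupled receptor
LDLR	plasma membrane	Transporter	Transporter
SH2B3	plasma membrane	Other	Other
CRBN	cytoplasm	Enzyme	E3 ligase
HDAC6	cytoplasm	Enzyme	Epigenetic enzyme
CYP19A1	cytoplasm	Enzyme	Monooxygenases
CYP17A1	cytoplasm	Enzyme	Monooxygenases
PSMB1	cytoplasm	Enzyme	Peptidase
PSMB2	cytoplasm	Enzyme	Peptidase
PSMB5	cytoplasm	Enzyme	Peptidase
PSMB8	cytoplasm	Enzyme	Peptidase
PSMB9	cytoplasm	Enzyme	Peptidase
PSMB10	cytoplasm	Enzyme	Peptidase
PIK3CD	cytoplasm	Enzyme	Phosphatidyl Inositol Kinases
BRAF	cytoplasm	Enzyme	Serine/threonine kinase
RAF1	cytoplasm	Enzyme	Serine/threonine kinase
MTOR	cytoplasm	Enzyme	Serine/threonine kinase
LIMK1	cytoplasm	Enzyme	Serine/threonine kinase
ITK	cytoplasm	Enzyme	Serine/threonine kinase
MAP2K1	cytoplasm	Enzyme	Threonine/tyrosine-protein kinase
MAP2K2	cytoplasm	Enzyme	Threonine/tyrosine-protein kinase
BCR-ABL	cytoplasm	Enzyme	Tyrosine kinase
ABL1	cytoplasm	Enzyme	Tyrosine kinase
JAK1	cytoplasm	Enzyme	Tyrosine kinase
JAK2	cytoplasm	Enzyme	Tyrosine kinase
BTK	cytoplasm	Enzyme	Tyrosine kinase
PSMD1	cytoplasm	Other	Other
PSMD2	cytoplasm	Other	Other
MAP1A	cytoplasm	Other	Other
MAP2	cytoplasm	Other	Other
HDAC1	nucleus	Enzyme	Epigenetic enzyme
HDAC2	nucleus	Enzyme	Epigenetic enzyme
HDAC3	nucleus	Enzyme	Epigenetic enzyme
DNMT1	nucleus	Enzyme	Epigenetic enzyme
PARP1	nucleus	Enzyme	Polymerase
PARP2	nucleus	Enzyme	Polymerase
PARP3	nucleus	Enzyme	Polymerase
RRM1	nucleus	Enzyme	Ribonucleotide diphosphate reductase
MAPK11	nucleus	Enzyme	Serine/threonine kinase
NEK11	nucleus	Enzyme	Serine/threonine kinase
SIK1	nucleus	Enzyme	Serine/threonine kinase
PTK6	nucleus	Enzyme	Tyrosine kinase
FRK	nucleus	Enzyme	Tyrosine kinase
AR	nucleus	Receptor	Ligand-dependent nuclear receptor
ESR1	nucleus	Receptor	Ligand-dependent nuclear receptor
ESR2	nucleus	Receptor	Ligand-dependent nuclear receptor
NR3C1	nucleus	Receptor	Ligand-dependent nuclear receptor
RARA	nucleus	Receptor	Ligand-dependent nuclear receptor
RARB	nucleus	Receptor	Ligand-dependent nuclear receptor
RARG	nucleus	Receptor	Ligand-dependent nuclear receptor
RXRA	nucleus	Receptor	Ligand-dependent nuclear receptor
RXRB	nucleus	Receptor	Ligand-dependent nuclear receptor
RXRG	nucleus	Receptor	Ligand-dependent nuclear receptor
TNFSF11	extracellular space	Cytokine	Cytokine
ACPP	extracellular space	Enzyme	Phosphatase
VEGFA	extracellular space	Growth factor	Growth factor
VEGFB	extracellular space	Growth factor	Growth factor
PGF	extracellular space	Growth factor	Growth factor
FGF1	extracellular space	Growth factor	Growth factor
GNRH1	extracellular space	Hormone	Hormone
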